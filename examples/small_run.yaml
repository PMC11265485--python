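# Reduced study design: seven reference noise models, 3 doses, 2 repeats,
# 14 slices of a 256x256 phantom. Runs in a few seconds.
source: simulate
baseline: FBP
reference: IR50
d_ref: 25.0
seed: 7
log_level: WARNING
design:
  algorithms: reference
  doses: [5, 15, 25]
  repeats: 2
  n_slices: 14
  thicknesses: [2.5]
layout:
  grid_size: [256, 256]
  body_semiaxes_mm: [80, 70]
  insert_center_mm: [-40, 0]
  lc_center_mm: [40, 0]
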