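# ctiq — quantitative CT image quality on a synthetic abdomen phantom

`ctiq` is a Python package for the objective image-quality metrics used to
compare CT reconstruction algorithms (filtered back projection, hybrid
iterative reconstruction, deep-learning reconstruction) on a
semi-anthropomorphic upper-abdomen phantom:

- **Noise and CNR** — per-ROI mean and sample SD of CT numbers (HU); the SD of
  a 41×41-pixel ROI in a homogeneous insert is the noise marker, and
  CNR = (μ₁ − μ₂)/σ contrasts the insert (μ₁ ≈ 58 HU) against the phantom
  background (μ₂ ≈ 18 HU).
- **Noise texture deviation (NTD, f₃σ)** — the fraction of ROI pixels with
  |pᵢ − p̄| > 3σ. Gaussian noise gives 2·(1 − Φ(3)) ≈ 2.7 × 10⁻³; elevated
  values flag the blotchy, non-Gaussian artifacts typical of aggressive
  iterative reconstruction.
- **Noise power spectrum (NPS)** — 2D spectra of detrended homogeneous-insert
  ROIs, NPS(u,v) = (ΔxΔy)/(NxNy)·⟨|DFT|²⟩, radially averaged to 1D and
  normalized by total power; summarized by the power-weighted mean frequency
  f_avg = Σ f·NPS(f)/Σ NPS(f) (lower f_avg = coarser texture).
- **Task-based transfer function (TTF)** — the circular-edge method on a
  15 mm, ~25 HU low-contrast lesion rod: radially binned edge spread function,
  differentiated to an LSF, tapered and Fourier-transformed; summarized by
  f₅₀, the frequency where the TTF drops to 0.5.
- **Dose-reduction potential** — per-algorithm OLS fits of
  ln σ = a + b ln D (CTDI_vol, mGy), equivalent dose
  D_equiv = exp((a_ref + b_ref ln D_ref − a_test)/b_test), and the saving
  Δ = D_ref − D_equiv with a delta-method 95% CI and Wald p-value.

Because the underlying study deposits no image data, the package ships a
first-class phantom simulator: a noiseless elliptical body (35 × 25 cm,
18 HU) with a homogeneous 5 cm insert (58 HU) and a low-contrast insert
(55 HU, with the 80 HU lesion rod), plus stationary colored Gaussian noise
with prescribed radial NPS shape, σ ∝ D^(−1/2)·T^(−1/2) dose/thickness
scaling, optional blotch artifacts, and controllable edge blur. Every
estimator is validated against this generator's known ground truth.

Intended users: medical-physics and image-quality researchers who want
tested, scriptable implementations of these metrics — for simulated stacks,
raw+JSON fixtures, or DICOM series (pixel spacing, slice thickness, rescale
slope/intercept honored).

## Worked example

Simulate a reduced study design (seven reconstruction-like noise models ×
3 dose levels × 2 repeats, 14 slices of a 256×256 phantom) and run the whole
pipeline:

```sh
ctiq analyze --config examples/small_run.yaml --out report --seed 7
ctiq report report
```

Selected output at the 25 mGy dose level (abridged):

```
algorithm  noise_mean  relative_cnr  ntd_mean     f_avg  pct_vs_baseline
      FBP      10.086         1.000  0.002827  0.300634            0.000
     IR50       6.791         1.485  0.003110  0.251050          -16.493
     IR90       4.266         2.379  0.004862  ...
      DLL       6.751         1.488  0.002893  0.294077           -2.181
      DLM       5.372         1.868  0.002827  0.287666           -4.314
      DLH       3.983         2.526  0.002558  0.282687           -5.970
```

Reading it: the DLR-like arms cut noise by 33/46/60% versus FBP, which lifts
relative CNR to ≈1.49/1.87/2.53 at equal contrast; their NTD stays at the
Gaussian floor (≈2.7 × 10⁻³) and their f_avg within a few percent of FBP,
i.e. noise texture is preserved. The IR-like arms reach similar noise but at
the price of elevated NTD (blotch artifacts, up to ≈4.9 × 10⁻³ for IR90) and
a 15–18% lower f_avg (coarser texture). The `dose_reduction.csv` table then
reports, e.g., the dose saving of the high-strength DLR arm relative to IR50
with its delta-method CI.

The same pipeline runs on your own data: point `source: fixtures` or
`source: dicom` at a directory of stacks (`ctiq validate DIR` lists what is
found), and the metrics, NPS/TTF curves and dose model are computed
identically.

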