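# Methods

## The measurement model

All metrics operate on stacks of axial CT slices in Hounsfield units (HU),
each stack tagged with its CTDI_vol dose (mGy), slice thickness (mm), pixel
spacing (mm) and a reconstruction-algorithm label. The unit of analysis is
the slice; nothing in the package models inter-slice correlation, because
every metric here is computed per slice (or pools slices as independent
samples).

### ROI statistics

The ROI layout follows the standard protocol for this phantom class: a
41×41-pixel (28.1 × 28.1 mm at the default 0.6854 mm spacing) square ROI at
the center of the homogeneous insert, four 21×21 ROIs at 0°/90°/180°/270°
around it, and one 21×21 ROI in the phantom background. The peripheral ROIs
sit at the largest axis-aligned radial offset that keeps them fully inside
the 50 mm insert (overlap with the central ROI is permitted; positions are
configurable). Per ROI we report the sample mean and SD (n−1 denominator);
the central-ROI SD is the noise marker.

- CNR = (μ_insert − μ_background)/σ_insert; undefined (NaN) at σ = 0.
- NTD (f₃σ) counts pixels with |pᵢ − p̄| **strictly** greater than 3σ, with
  p̄ and σ from the ROI itself; a constant ROI has NTD 0. The per-slice NTD
  is the average over the five insert ROIs by default (central-only is an
  option; a pixel-pooled variant is provided for large-sample checks).
  Under Gaussian noise the expectation is 2·(1 − Φ(3)) ≈ 2.6998 × 10⁻³.
- Homogeneity = max − min of the five insert-ROI means; the background ROI
  is excluded by definition.
- Group comparisons use Welch's unequal-variance two-sample t-test at
  α = 0.05 (the variant is a package choice; with zero variance in both
  groups and equal means, t = 0, p = 1 by convention).
- Aggregation pools all slices of all repeat scans within an
  (algorithm, dose, thickness) cell; relative CNR divides each cell's mean
  CNR by the baseline algorithm's mean CNR at the same dose level (the
  baseline may have a different slice thickness, which supports thin-slice
  versus conventional-slice comparisons).

### Noise power spectrum

Four 32×32 ROIs in quadrant arrangement inside the homogeneous insert, on
every analyzed slice (ROI size/positions configurable; the insert is small,
so these ROIs are the largest that fit with margin). Each ROI is detrended
and transformed:

    NPS(u, v) = (Δx·Δy)/(Nx·Ny) · ⟨|DFT(ROI)|²⟩,

averaged over all ROIs of all slices of a scan. Detrending defaults to
removing a first-order polynomial surface per ROI — the community norm for
anthropomorphic phantoms, whose low-order HU gradients would otherwise leak
into the low-frequency bins; "mean" and "none" are selectable. No spectral
window is applied before the DFT (a window biases total power, and at these
ROI sizes detrending handles the leakage); this is exposed as a design
constant rather than a switch worth flipping in practice.

The radial average uses bins of one DFT-bin width, Δf = 1/(w·Δx), assigns
each 2D sample to its nearest bin by radius, drops bins beyond Nyquist or
with no samples (no interpolation), and spans [0, Nyquist]. Repeat scans at
one condition are averaged first, then normalized by total power (the
literal reading of the stated order of operations), so the nNPS integrates
to one. The texture scalar is f_avg = Σ f·NPS(f)/Σ NPS(f) over the 1D bins.
Parseval holds to within the detrending loss: the 2D-spectrum total power
matches the mean detrended ROI variance (tested at 15%, typically ≪ 1%).

### Task-based transfer function

Circular-edge method on the 15 mm lesion (80 HU versus 55 HU insert
background, ≈ 25 HU contrast — a deliberately low-contrast task). The lesion
center is found to subpixel precision as the intensity-weighted centroid of
pixels above the half-contrast threshold (works for hyper- and
hypo-attenuating lesions). Pixels from the ten consecutive slices covering
the 3 cm rod are pooled and binned by radial distance in bins of 0.25 px
(0.171 mm), the standard circular-edge oversampling; interior empty bins are
filled by linear interpolation and the call is rejected if more than 30% of
bins are empty. The radial ROI extends to 1.8 lesion radii, below the
2-radius limit at which neighbouring structures intrude.

The ESF is optionally monotone-conditioned (isotonic regression; off for
noiseless data, on by default in the pipeline), differentiated by central
finite differences, tapered with a full-span Hann window, zero-padded to
≥1024 samples and Fourier-transformed; TTF = |DFT| normalized to 1 at zero
frequency. f₅₀ is the linearly interpolated first downward crossing of 0.5;
if the TTF never falls below 0.5 in band, f₅₀ is reported as "not reached"
(None), distinct from an error. Per-scan TTFs are averaged pointwise across
repeats and f₅₀ recomputed on the averaged curve.

**Known bias.** For a Gaussian PSF of width σ the closed form is
f₅₀ = √(ln 2/(2π²σ²)). The circular-edge estimate carries an intrinsic
curvature bias that grows with σ/R (R = 7.5 mm): verified against an
analytic Bessel-integral blurred-disk oracle, the bias is +0.7% at
σ = 0.6 mm, +2.8% at 0.8 mm and +7.6% at 1.2 mm. Closed-form recovery
within 5% therefore holds for σ ≲ 0.9 mm, which covers the simulator's
blur range (0.45–0.8 mm). Curve averaging across three noisy repeats
reduces f₅₀ RMSE relative to taking the median single-scan f₅₀ (≈0.0073 vs
0.0082 mm⁻¹ in a 120-trial simulation at realistic 25 mGy noise), though
the per-trial win probability is only ≈0.57 — mean-of-three and
median-of-three are highly correlated estimators.

### Noise–dose model and dose-reduction potential

Per algorithm, ln(noise) is regressed on ln(dose) by OLS (statsmodels),
using per-scan mean noise as observations — 15 points for the full
3-repeat × 5-dose design. Per-slice observations would inflate n
unrealistically, since slices of one scan share the same realization of the
scanner state; a per-slice mode exists but is not the default.

Equivalent dose and saving are closed-form functions of the two fits (see
README). The 95% CI propagates the 4-vector (a_t, b_t, a_r, b_r) covariance
— block-diagonal across the two independent fits — through the gradient of
Δ (delta method), with the normal 1.96 quantile matching the method's
asymptotics (a t-quantile mode exists). Treating the reference fit as
random is the conservative default; a fixed-reference mode supports
sensitivity analysis. Percentages are reported at full precision with a
rounded column for summary tables.

`ci_coverage_check` validates the interval end to end: it simulates the
full repeated-dose design from a known truth (lognormal scatter of per-scan
noise), refits both arms, and reports empirical coverage. Under the default
truth, coverage is ≈0.93–0.95 over 500 simulations; it is robust to a
misspecified dose exponent because the slope is fitted, never imposed. The
coverage comparison uses an absolute slack of 1e-9·(1 + |Δ|) so the
degenerate zero-scatter design, where the CI collapses to a point, is
judged on exact recovery up to roundoff.

## The phantom simulator

The generator emulates the study conditions, not scanner physics:

- Geometry: 512×512 grid at 0.6854 mm spacing (back-computed from the
  41-px/28.1-mm ROI), elliptical body 350 × 250 mm at 18 HU, air −1000 HU
  outside, homogeneous 50 mm insert at 58 HU, low-contrast insert at 55 HU
  with a 15 mm, 80 HU lesion rod spanning 30 mm axially (12 slices at
  2.5 mm). Pixel (i, j) has its center at ((i+0.5)·Δx, (j+0.5)·Δx); every
  voxel takes the HU of the region containing its center, so the noiseless
  render is piecewise constant and perfectly homogeneous by construction.
- Noise: per-slice independent colored Gaussian fields, built by weighting
  white noise in the frequency domain with √NPS(f) and rescaling the sample
  SD to σ = σ_ref·(D/D_ref)^(−1/2)·(T/T_ref)^(−1/2). Shape families: "white"
  and the ramp-Gaussian NPS(f) ∝ f·exp(−(f/f_c)²), which covers FBP-like
  (higher f_c) through IR-like (lower f_c) textures; `calibrate_shape`
  solves for f_c hitting a target f_avg to 1e-4 mm⁻¹ by Brent root-finding
  on the band-limited analytic integral. Attainable ramp-Gaussian f_avg is
  (0, 2/3·Nyquist).
- Thin slices (0.625 mm) are modelled solely by the thickness exponent
  (noise ×2 versus 2.5 mm); this matches the empirical observation that
  thin-slice high-strength DLR noise lands near conventional-slice FBP/IR50.
- Blotch artifacts: a zero-mean Poisson field of random-sign Gaussian bumps
  (density per mm², width 1.6 mm), superimposed on IR-like arms to push NTD
  above the Gaussian floor. Amplitudes are expressed relative to the local
  Gaussian σ so NTD stays roughly dose-independent, as observed for real IR.
  The built-in IR50/IR70/IR90 models were calibrated once to land NTD near
  3.3/4.0/5.1 × 10⁻³. This is an emulation device — no claim is made about
  the actual artifact mechanism of any vendor algorithm.
- Edge blur: the noiseless structure is blurred per slice with a Gaussian
  PSF (σ in mm) before noise is added; the built-in models use 0.45 mm
  (FBP-like) to 0.8 mm (IR90-like), reproducing the reported ordering of
  edge sharpness (FBP > DLR > IR).
- Seeding: one master seed per scan; slice k draws from
  `SeedSequence(entropy=seed, spawn_key=(k,))`, so any slice is
  reproducible in isolation and stacks are bit-identical across reruns. In
  the pipeline, scan k of the sorted condition list uses
  `SeedSequence([master, k])`, making results independent of execution
  order.

What the generator does **not** emulate: projection-domain physics (scatter,
beam hardening, photon starvation), nonstationary noise across the field of
view, inter-slice noise correlation, and the actual nonlinear behaviour of
iterative or deep-learning reconstructions. Passing tests therefore
demonstrate that the estimators are correct on stationary colored-Gaussian
(plus blotch) fields with known ground truth — not that any particular
scanner or algorithm attains these numbers on real data.

## I/O

Stacks round-trip through two formats: a raw little-endian float32 array
(`<scan_id>.raw`, C-order slices×rows×cols) with a JSON sidecar carrying
spacing/thickness/dose/algorithm/seed (bit-exact), and a DICOM series (one
CT file per slice, signed int16 with RescaleSlope 1 / RescaleIntercept
−1024, exact to ±0.5 HU by integer quantization; signed storage avoids
clipping noisy air voxels). Missing sidecar fields are rejected by name.

## Problem sizes

The test suite and acceptance script run reduced designs chosen to keep the
statistics meaningful: a 256×256 phantom with the same pixel spacing and
insert geometry for simulation-heavy tests, 14-slice stacks (12 lesion
slices), 16–64 noise ROIs per spectrum estimate, 120 slices per arm for the
CNR-ratio checks, 500 simulations for CI coverage, 2000 bootstrap
replicates, and 30–50 Monte-Carlo repeats for the TTF robustness checks.
The full study-scale design (7 algorithms × 5 doses × 3 repeats × 40
slices = 4200 images) is expressed by the default `SimDesign` and runs
through the identical code path.

## Known limitations

- NTD's Gaussian floor is an asymptotic value; at 41×41 = 1681 pixels the
  small-sample bias is below the 5% test tolerance but not zero.
- The TTF at low contrast-to-noise is fragile; the pipeline mitigates with
  monotone conditioning and repeat averaging, and the mean f₅₀ over 50
  noisy repeats stays within 10% of the noiseless value at study-realistic
  noise, but single noisy scans can miss by more.
- The dose model assumes lognormal residuals and independence between arms;
  arms reconstructed from the same raw data violate independence, which
  would make the delta-method CI conservative in the difference.
- f_avg of the 1D NPS uses unweighted bin sums; with equal-width bins this
  is the discrete analogue of the integral definition, but estimates within
  half a bin of an analytic target should be considered equivalent.
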