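"""Synthetic semi-anthropomorphic abdomen phantom and CT noise simulator.

Renders a noiseless elliptical "upper abdomen" phantom (background ~18 HU)
carrying two cylindrical 5-cm inserts — a homogeneous insert (~58 HU) and a
low-contrast insert (55 HU background with a 15 mm, 80 HU central lesion rod) —
and synthesizes stationary colored Gaussian noise whose magnitude scales with
dose and slice thickness as a power law and whose radial noise power spectrum
(NPS) follows a prescribed shape family. Different reconstruction algorithms
(FBP-like, hybrid-IR-like, DLR-like) are emulated purely through their noise
texture and magnitude; no projection-domain physics is simulated.

Geometry conventions: 0-based pixel indices, pixel (i, j) has its physical
center at ((i + 0.5) * spacing, (j + 0.5) * spacing) with i the row (anterior-
posterior) and j the column (lateral) index; all geometry is in millimetres,
relative positions are taken from the body-ellipse center at the grid center.
Air outside the body outline is -1000 HU. HU are stored as float32.

Seeding: each scan takes one master seed; the noise stream of slice ``k`` is
drawn from ``numpy.random.SeedSequence(entropy=seed, spawn_key=(k,))`` so any
slice is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import integrate, ndimage, optimize

AIR_HU = -1000.0

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry and nominal HU of the phantom cross-section.

    Distances are mm; positions are (x=lateral, y=anterior-posterior) offsets
    from the body-ellipse center. The default pixel spacing 0.6854 mm is
    back-computed from a 41-pixel ROI spanning 28.1 mm.
    """

    grid_size: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_spacing: float = 28.1 / 41.0  # mm
    body_semiaxes_mm: tuple[float, float] = (175.0, 125.0)  # (lateral, AP)
    background_hu: float = 18.0
    insert_center_mm: tuple[float, float] = (-60.0, 0.0)
    insert_diameter_mm: float = 50.0
    insert_hu: float = 58.0
    lc_center_mm: tuple[float, float] = (60.0, 0.0)
    lc_diameter_mm: float = 50.0
    lc_background_hu: float = 55.0
    lesion_diameter_mm: float = 15.0
    lesion_hu: float = 80.0
    lesion_extent_mm: float = 30.0  # axial length of the lesion rod

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_spacing)

    def validate(self) -> None:
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        for v in (self.background_hu, self.insert_hu, self.lc_background_hu,
                  self.lesion_hu):
            if not math.isfinite(v):
                raise ValueError("all HU values must be finite")
        a, b = self.body_semiaxes_mm
        ny, nx = self.grid_size
        half_x = nx * self.pixel_spacing / 2.0
        half_y = ny * self.pixel_spacing / 2.0
        if a > half_x or b > half_y:
            raise ValueError(
                f"grid {self.grid_size} too small to contain body outline "
                f"({2 * a:.1f} x {2 * b:.1f} mm at {self.pixel_spacing} mm/px)")
        for (cx, cy), diam in (
                (self.insert_center_mm, self.insert_diameter_mm),
                (self.lc_center_mm, self.lc_diameter_mm)):
            r = diam / 2.0
            theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
            px = cx + r * np.cos(theta)
            py = cy + r * np.sin(theta)
            if np.any((px / a) ** 2 + (py / b) ** 2 > 1.0):
                raise ValueError("inserts must lie fully inside the body outline")


@dataclass(frozen=True)
class NpsShape:
    """Radial NPS shape family for noise synthesis.

    "fbp-like" and "ir-like" share the ramp-Gaussian form
    NPS(f) ∝ f * exp(-(f / f_c)^2); IR-like textures simply use a smaller
    characteristic frequency f_c. "white" is flat and takes no parameter.
    """

    family: str = "fbp-like"
    f_c: float | None = 0.35  # mm^-1; None for white

    def __post_init__(self):
        if self.family not in ("fbp-like", "ir-like", "white"):
            raise ValueError(f"unknown NPS shape family {self.family!r}")
        if self.family != "white" and (self.f_c is None or self.f_c <= 0):
            raise ValueError("f_c must be > 0 for ramp-Gaussian families")

    def density(self, f: np.ndarray) -> np.ndarray:
        """Unnormalized radial NPS shape evaluated at frequency f (mm^-1)."""
        f = np.asarray(f, dtype=float)
        if self.family == "white":
            return np.ones_like(f)
        return f * np.exp(-((f / self.f_c) ** 2))


@dataclass(frozen=True)
class Blotch:
    """Sparse zero-mean Gaussian-bump artifact field (IR-style blotches).

    With ``relative`` set, ``amplitude`` is expressed in units of the
    Gaussian noise SD at the simulated condition instead of HU, which keeps
    the resulting noise texture deviation roughly dose-independent — the
    behaviour observed for iterative reconstruction artifacts.
    """

    density: float  # bumps per mm^2
    amplitude: float  # HU, or multiples of sigma if relative
    width: float  # mm (Gaussian sigma of each bump)
    relative: bool = False


@dataclass(frozen=True)
class NoiseModel:
    """Per-algorithm noise magnitude and texture description.

    ``sigma_ref`` is the noise SD (HU) at dose ``d_ref`` (mGy) and slice
    thickness ``thickness_ref`` (mm); at other conditions
    sigma = sigma_ref * (dose/d_ref)**dose_exponent
                      * (thickness/thickness_ref)**thickness_exponent.
    """

    label: str
    sigma_ref: float
    d_ref: float = 25.0
    thickness_ref: float = 2.5
    dose_exponent: float = -0.5
    thickness_exponent: float = -0.5
    nps_shape: NpsShape = field(default_factory=NpsShape)
    blotch: Blotch | None = None
    edge_blur_sigma: float = 0.0  # mm, PSF blur of the noiseless structure

    def __post_init__(self):
        if self.sigma_ref < 0:
            raise ValueError("sigma_ref must be >= 0")
        if self.d_ref <= 0 or self.thickness_ref <= 0:
            raise ValueError("reference dose and thickness must be > 0")

    def sigma_at(self, dose: float, thickness: float) -> float:
        if dose <= 0 or thickness <= 0:
            raise ValueError("dose and thickness must be > 0")
        return (self.sigma_ref
                * (dose / self.d_ref) ** self.dose_exponent
                * (thickness / self.thickness_ref) ** self.thickness_exponent)


@dataclass
class ImageStack:
    """A stack of axial CT slices in HU plus its acquisition metadata."""

    voxels: np.ndarray  # (slices, rows, cols) float32 HU
    pixel_spacing: float  # mm
    slice_thickness: float  # mm
    dose_ctdi: float  # mGy
    algorithm: str
    scan_id: str = "scan"
    seed: int | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (slices, rows, cols) array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("all voxels must be finite")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


# ---------------------------------------------------------------------------
# Noiseless rendering
# ---------------------------------------------------------------------------


def _pixel_coords_mm(layout: PhantomLayout) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) mm of every pixel center relative to the body-ellipse center."""
    ny, nx = layout.grid_size
    s = layout.pixel_spacing
    y = (np.arange(ny) + 0.5) * s - ny * s / 2.0
    x = (np.arange(nx) + 0.5) * s - nx * s / 2.0
    return np.meshgrid(x, y)  # xx varies along columns, yy along rows


def lesion_slice_mask(layout: PhantomLayout, n_slices: int,
                      slice_thickness: float) -> np.ndarray:
    """Boolean mask of slices whose center lies within the lesion rod.

    The rod is centered axially in the stack.
    """
    z = (np.arange(n_slices) + 0.5 - n_slices / 2.0) * slice_thickness
    return np.abs(z) <= layout.lesion_extent_mm / 2.0


def render_phantom(layout: PhantomLayout, n_slices: int,
                   slice_thickness: float = 2.5) -> ImageStack:
    """Render the noiseless phantom: piecewise-constant HU per region.

    Every voxel takes the HU of the region containing its pixel center; air
    (-1000 HU) fills the grid outside the body ellipse. The low-contrast
    lesion appears only on slices intersecting its 3-cm rod.
    """
    layout.validate()
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    xx, yy = _pixel_coords_mm(layout)
    a, b = layout.body_semiaxes_mm
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0

    def disk(center, diameter):
        cx, cy = center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= (diameter / 2.0) ** 2

    base = np.full(layout.grid_size, AIR_HU, dtype=np.float32)
    base[body] = layout.background_hu
    base[disk(layout.insert_center_mm, layout.insert_diameter_mm)] = layout.insert_hu
    lc = disk(layout.lc_center_mm, layout.lc_diameter_mm)
    base[lc] = layout.lc_background_hu
    lesion = disk(layout.lc_center_mm, layout.lesion_diameter_mm)

    with_lesion = base.copy()
    with_lesion[lesion] = layout.lesion_hu

    mask = lesion_slice_mask(layout, n_slices, slice_thickness)
    voxels = np.empty((n_slices,) + layout.grid_size, dtype=np.float32)
    voxels[~mask] = base
    voxels[mask] = with_lesion
    return ImageStack(voxels, layout.pixel_spacing, slice_thickness,
                      dose_ctdi=0.0, algorithm="noiseless", scan_id="noiseless")


# ---------------------------------------------------------------------------
# Colored-noise synthesis and spectral calibration
# ---------------------------------------------------------------------------


def analytic_favg(shape: NpsShape, spacing: float) -> float:
    """Power-weighted mean frequency of a shape band-limited to [0, Nyquist].

    f_avg = ∫ f·NPS(f) df / ∫ NPS(f) df evaluated by adaptive quadrature;
    this is the continuous analogue of the discrete radial-NPS estimator.
    """
    f_n = 1.0 / (2.0 * spacing)
    num, _ = integrate.quad(lambda f: f * shape.density(f), 0.0, f_n)
    den, _ = integrate.quad(lambda f: shape.density(f), 0.0, f_n)
    return num / den


def calibrate_shape(target_favg: float, family: str, spacing: float,
                    tol: float = 1e-4) -> NpsShape:
    """Solve for the f_c whose band-limited analytic f_avg hits the target.

    Uses scalar root bracketing (Brent) on the monotone map f_c -> f_avg.
    The white family has no parameter and only admits f_avg = Nyquist/2.
    """
    f_n = 1.0 / (2.0 * spacing)
    if not 0.0 < target_favg < f_n:
        raise ValueError(f"target f_avg must lie in (0, Nyquist={f_n:.3f})")
    if family == "white":
        if abs(target_favg - f_n / 2.0) > tol:
            raise ValueError(
                "white noise has fixed f_avg = Nyquist/2; target unattainable")
        return NpsShape("white", None)
    # ramp-Gaussian f_avg spans (0, 2*f_N/3) as f_c goes 0 -> inf
    upper = 2.0 * f_n / 3.0
    if target_favg >= upper - tol:
        raise ValueError(
            f"target f_avg {target_favg} unattainable for {family} "
            f"(supremum {upper:.4f} mm^-1)")

    def err(f_c):
        return analytic_favg(NpsShape(family, f_c), spacing) - target_favg

    lo, hi = 1e-3, 1e3
    f_c = optimize.brentq(err, lo, hi, xtol=1e-10)
    return NpsShape(family, f_c)


def synthesize_noise(shape: tuple[int, int], spacing: float, model: NoiseModel,
                     dose: float, thickness: float,
                     rng: np.random.Generator | int) -> np.ndarray:
    """Zero-mean colored Gaussian noise field with prescribed SD and spectrum.

    White Gaussian noise is weighted in the frequency domain by the square
    root of the target radial NPS shape, transformed back, and rescaled so
    the sample SD equals sigma_ref scaled by the dose/thickness power laws.
    """
    if min(shape) < 64:
        raise ValueError("noise field must be at least 64x64")
    sigma = model.sigma_at(dose, thickness)
    if sigma <= 0:
        raise ValueError("target noise SD must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=spacing)
    fx = np.fft.fftfreq(nx, d=spacing)
    fr = np.hypot(*np.meshgrid(fx, fy))
    weight = np.sqrt(model.nps_shape.density(fr))
    weight[0, 0] = 0.0  # no DC power: noise is zero-mean by construction
    white = rng.standard_normal(shape)
    colored = np.fft.ifft2(np.fft.fft2(white) * weight).real
    colored -= colored.mean()
    sd = colored.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate spectral weight: zero-variance field")
    return colored * (sigma / sd)


def blotch_field(shape: tuple[int, int], spacing: float, blotch: Blotch,
                 rng: np.random.Generator) -> np.ndarray:
    """Sparse zero-mean field of random-sign Gaussian bumps.

    Bump count is Poisson with mean density*area; used to push the noise
    texture deviation above the Gaussian floor, emulating the blotchy
    artifacts of aggressive iterative reconstruction.
    """
    ny, nx = shape
    area = ny * nx * spacing ** 2
    n_bumps = rng.poisson(blotch.density * area)
    out = np.zeros(shape)
    if n_bumps == 0:
        return out
    cy = rng.uniform(0, ny * spacing, n_bumps)
    cx = rng.uniform(0, nx * spacing, n_bumps)
    signs = rng.choice([-1.0, 1.0], n_bumps)
    half = max(1, int(np.ceil(4 * blotch.width / spacing)))
    yc = (np.arange(ny) + 0.5) * spacing
    xc = (np.arange(nx) + 0.5) * spacing
    for k in range(n_bumps):
        i0 = int(cy[k] / spacing)
        j0 = int(cx[k] / spacing)
        i_lo, i_hi = max(0, i0 - half), min(ny, i0 + half + 1)
        j_lo, j_hi = max(0, j0 - half), min(nx, j0 + half + 1)
        dy = yc[i_lo:i_hi, None] - cy[k]
        dx = xc[None, j_lo:j_hi] - cx[k]
        out[i_lo:i_hi, j_lo:j_hi] += (
            signs[k] * blotch.amplitude
            * np.exp(-(dy ** 2 + dx ** 2) / (2 * blotch.width ** 2)))
    return out - out.mean()


def slice_rng(seed: int, k: int) -> np.random.Generator:
    """Noise stream for slice k of a scan with the given master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(k,)))


def simulate_scan(layout: PhantomLayout, model: NoiseModel, dose: float,
                  thickness: float, n_slices: int, seed: int,
                  scan_id: str | None = None) -> ImageStack:
    """Render, blur, and add per-slice noise: one complete simulated scan.

    The noiseless structure is blurred with the model's PSF sigma (emulating
    reconstruction-dependent edge softness), then an independent colored
    noise field — plus optional blotch artifacts — is added to every slice.
    Deterministic given (layout, model, dose, thickness, n_slices, seed).
    """
    stack = render_phantom(layout, n_slices, thickness)
    structure = stack.voxels.astype(np.float64)
    if model.edge_blur_sigma > 0:
        sig_px = model.edge_blur_sigma / layout.pixel_spacing
        for k in range(n_slices):
            structure[k] = ndimage.gaussian_filter(structure[k], sig_px,
                                                   mode="nearest")
    if model.sigma_ref > 0:
        for k in range(n_slices):
            rng = slice_rng(seed, k)
            noise = synthesize_noise(layout.grid_size, layout.pixel_spacing,
                                     model, dose, thickness, rng)
            if model.blotch is not None:
                b = model.blotch
                if b.relative:
                    b = replace(b, amplitude=b.amplitude
                                * model.sigma_at(dose, thickness),
                                relative=False)
                noise = noise + blotch_field(layout.grid_size,
                                             layout.pixel_spacing, b, rng)
            structure[k] += noise
    if scan_id is None:
        scan_id = f"{model.label}_d{dose:g}_t{thickness:g}_s{seed}"
    return ImageStack(structure.astype(np.float32), layout.pixel_spacing,
                      thickness, dose_ctdi=dose, algorithm=model.label,
                      scan_id=scan_id, seed=seed)


# ---------------------------------------------------------------------------
# Fixture and DICOM I/O
# ---------------------------------------------------------------------------

_SIDECAR_FIELDS = ("shape", "pixel_spacing", "slice_thickness", "dose_ctdi",
                   "algorithm", "scan_id", "seed")


def write_fixture(stack: ImageStack, directory: str | Path) -> Path:
    """Write <scan_id>.raw (float32 C-order) + <scan_id>.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw = directory / f"{stack.scan_id}.raw"
    stack.voxels.astype("<f4").tofile(raw)
    sidecar = {
        "shape": list(stack.voxels.shape),
        "pixel_spacing": stack.pixel_spacing,
        "slice_thickness": stack.slice_thickness,
        "dose_ctdi": stack.dose_ctdi,
        "algorithm": stack.algorithm,
        "scan_id": stack.scan_id,
        "seed": stack.seed,
    }
    (directory / f"{stack.scan_id}.json").write_text(
        json.dumps(sidecar, indent=1))
    return raw


def read_fixture(path: str | Path) -> ImageStack:
    """Read a raw+JSON fixture; ``path`` is the .raw, .json, or basename."""
    path = Path(path)
    name = path.name
    for suffix in (".raw", ".json"):  # scan ids may themselves contain dots
        if name.endswith(suffix):
            name = name[:-len(suffix)]
    base = path.parent / name
    sidecar_path = base.parent / f"{base.name}.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for fld in _SIDECAR_FIELDS:
        if fld not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {fld!r}")
    voxels = np.fromfile(base.parent / f"{base.name}.raw", dtype="<f4")
    voxels = voxels.reshape(meta["shape"])
    return ImageStack(voxels, meta["pixel_spacing"], meta["slice_thickness"],
                      meta["dose_ctdi"], meta["algorithm"], meta["scan_id"],
                      meta["seed"])


def write_dicom_series(stack: ImageStack, directory: str | Path) -> Path:
    """Write one CT DICOM file per slice (int16 + rescale slope/intercept).

    HU are stored as round(HU + 1024) in signed 16-bit with RescaleSlope 1
    and RescaleIntercept -1024, so a round trip is exact to +/- 0.5 HU.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import (CTImageStorage, ExplicitVRLittleEndian,
                             generate_uid)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    extras = json.dumps({"scan_id": stack.scan_id, "seed": stack.seed,
                         "algorithm": stack.algorithm,
                         "dose_ctdi": stack.dose_ctdi})
    for k in range(stack.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.SeriesDescription = stack.algorithm
        ds.ImageComments = extras
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * stack.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [stack.pixel_spacing, stack.pixel_spacing]
        ds.SliceThickness = stack.slice_thickness
        ds.CTDIvol = stack.dose_ctdi
        ds.Rows, ds.Columns = stack.voxels.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        stored = np.clip(np.round(stack.voxels[k].astype(np.float64) + 1024.0),
                         -32768, 32767).astype(np.int16)
        ds.PixelData = stored.tobytes()
        pydicom.dcmwrite(directory / f"{stack.scan_id}_{k:04d}.dcm", ds,
                         enforce_file_format=True)
    return directory


def read_dicom_series(directory: str | Path) -> ImageStack:
    """Read a single-series DICOM directory back into an ImageStack."""
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    first = datasets[0]
    extras = json.loads(str(first.ImageComments))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slices.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    return ImageStack(np.stack(slices), float(first.PixelSpacing[0]),
                      float(first.SliceThickness),
                      float(extras["dose_ctdi"]), extras["algorithm"],
                      extras["scan_id"], extras["seed"])


# ---------------------------------------------------------------------------
# Reference noise models (texture per algorithm family)
# ---------------------------------------------------------------------------


def reference_noise_models(layout: PhantomLayout | None = None,
                           sigma_fbp: float = 10.0,
                           d_ref: float = 25.0) -> dict[str, NoiseModel]:
    """Seven noise models emulating FBP, hybrid IR (3 blends), DLR (3 strengths).

    Noise magnitudes follow the reported average reductions relative to FBP
    (IR paralleling DLR: ~33/46/60% for low/medium/high strength); textures
    are calibrated so FBP-like f_avg ≈ 0.30 mm^-1, hybrid IR steps down to
    ≈ 0.19 mm^-1, and DLR stays within a few percent of FBP. Hybrid IR
    additionally carries blotch artifacts that raise NTD above the Gaussian
    floor; edge blur increases with IR blend and (less) with DLR strength.
    """
    spacing = (layout.pixel_spacing if layout is not None
               else PhantomLayout.pixel_spacing)

    def shape(favg):
        return calibrate_shape(favg, "fbp-like", spacing)

    return {
        "FBP": NoiseModel("FBP", sigma_fbp, d_ref, nps_shape=shape(0.30),
                          edge_blur_sigma=0.45),
        "IR50": NoiseModel("IR50", sigma_fbp * 0.67, d_ref,
                           nps_shape=shape(0.26),
                           blotch=Blotch(0.0005, 3.0, 1.6, relative=True),
                           edge_blur_sigma=0.60),
        "IR70": NoiseModel("IR70", sigma_fbp * 0.54, d_ref,
                           nps_shape=shape(0.23),
                           blotch=Blotch(0.001, 3.2, 1.6, relative=True),
                           edge_blur_sigma=0.70),
        "IR90": NoiseModel("IR90", sigma_fbp * 0.40, d_ref,
                           nps_shape=shape(0.19),
                           blotch=Blotch(0.002, 3.3, 1.6, relative=True),
                           edge_blur_sigma=0.80),
        "DLL": NoiseModel("DLL", sigma_fbp * 0.67, d_ref,
                          nps_shape=shape(0.295), edge_blur_sigma=0.52),
        "DLM": NoiseModel("DLM", sigma_fbp * 0.54, d_ref,
                          nps_shape=shape(0.29), edge_blur_sigma=0.55),
        "DLH": NoiseModel("DLH", sigma_fbp * 0.40, d_ref,
                          nps_shape=shape(0.28), edge_blur_sigma=0.60),
    }
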