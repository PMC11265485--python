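"""Per-image ROI statistics: noise, CNR, NTD, homogeneity, and aggregation.

The ROI layout mirrors the study protocol: one 41x41-pixel square ROI at the
center of the homogeneous insert, four 21x21 ROIs in its periphery at 90-degree
spacings, and one 21x21 ROI in the phantom background. Per ROI the mean and
sample SD of the CT numbers are computed (SD is the noise marker), plus the
noise texture deviation

    NTD = f_3sigma = (1/n) * #{ i : |p_i - pbar| > 3*sigma },

the fraction of ROI pixels deviating strictly more than three sample SDs from
the ROI mean — for Gaussian noise this converges to 2*(1 - Phi(3)) ~ 0.0027,
and elevated values flag non-Gaussian (blotchy, IR-specific) texture. CNR is
(mu_insert - mu_background) / sigma_insert. Homogeneity is the max difference
between the mean CT numbers of the five insert ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import ImageStack, PhantomLayout

# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Roi:
    """Axis-aligned pixel-coordinate ROI: top-left corner plus size."""

    row: int
    col: int
    height: int
    width: int

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @classmethod
    def centered(cls, center_row: int, center_col: int, size: int) -> "Roi":
        half = size // 2
        return cls(center_row - half, center_col - half, size, size)


@dataclass(frozen=True)
class RoiSet:
    central: Roi  # 41x41 at homogeneous-insert center
    peripheral: tuple[Roi, ...]  # four 21x21 inside the insert
    background: Roi  # one 21x21 in phantom background

    @property
    def insert_rois(self) -> tuple[Roi, ...]:
        return (self.central,) + self.peripheral


def _center_px(layout: PhantomLayout, pos_mm: tuple[float, float]) -> tuple[int, int]:
    ny, nx = layout.grid_size
    s = layout.pixel_spacing
    col = int(round(pos_mm[0] / s + nx / 2.0 - 0.5))
    row = int(round(pos_mm[1] / s + ny / 2.0 - 0.5))
    return row, col


def default_roi_layout(layout: PhantomLayout, central_size: int = 41,
                       small_size: int = 21) -> RoiSet:
    """Protocol ROI placement derived from the phantom geometry.

    The four peripheral ROIs sit at 0/90/180/270 degrees from the insert
    center, at the largest radial offset that keeps each ROI fully inside
    the insert; overlap with the central ROI is permitted. The background
    ROI sits at the body center, between the two inserts.
    """
    s = layout.pixel_spacing
    r_insert_px = layout.insert_diameter_mm / 2.0 / s
    cr, cc = _center_px(layout, layout.insert_center_mm)
    half = small_size / 2.0
    # axis-aligned offset: farthest ROI corner at sqrt((off+half)^2 + half^2)
    max_off = math.sqrt(max(r_insert_px ** 2 - half ** 2, 0.0)) - half
    off = int(math.floor(max_off))
    if off <= 0:
        raise ValueError("insert too small for the peripheral ROI layout")
    peripheral = (
        Roi.centered(cr, cc + off, small_size),
        Roi.centered(cr - off, cc, small_size),
        Roi.centered(cr, cc - off, small_size),
        Roi.centered(cr + off, cc, small_size),
    )
    br, bc = _center_px(layout, (0.0, 0.0))
    return RoiSet(central=Roi.centered(cr, cc, central_size),
                  peripheral=peripheral,
                  background=Roi.centered(br, bc, small_size))


def extract_roi(image: np.ndarray, roi: Roi) -> np.ndarray:
    """Exact pixel block of a 2D image; no interpolation."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("extract_roi expects a single 2D slice")
    if (roi.row < 0 or roi.col < 0
            or roi.row + roi.height > image.shape[0]
            or roi.col + roi.width > image.shape[1]):
        raise ValueError(f"ROI {roi} exceeds image bounds {image.shape}")
    return image[roi.row:roi.row + roi.height, roi.col:roi.col + roi.width]


# ---------------------------------------------------------------------------
# Per-ROI statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiStats:
    mean: float  # HU
    sd: float  # HU, sample SD (noise marker)
    ntd: float  # fraction of pixels beyond 3 sample SDs
    n: int


def ntd(pixels: np.ndarray) -> float:
    """Noise texture deviation f_3sigma of one ROI.

    Sample mean and SD (n-1 denominator) of the ROI itself; strict
    inequality in the count. A constant ROI has NTD 0.
    """
    p = np.asarray(pixels, dtype=float).ravel()
    if p.size < 2:
        raise ValueError("NTD needs at least 2 pixels")
    sd = p.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(np.count_nonzero(np.abs(p - p.mean()) > 3.0 * sd) / p.size)


def pooled_ntd(roi_blocks: list[np.ndarray]) -> float:
    """Pixel-pooled NTD variant: total exceedance count / total pixels.

    Each ROI keeps its own mean and SD; only the counts are pooled.
    """
    exceed = 0
    total = 0
    for block in roi_blocks:
        p = np.asarray(block, dtype=float).ravel()
        sd = p.std(ddof=1)
        if sd > 0:
            exceed += int(np.count_nonzero(np.abs(p - p.mean()) > 3.0 * sd))
        total += p.size
    if total == 0:
        raise ValueError("no pixels")
    return exceed / total


def roi_stats(pixels: np.ndarray) -> RoiStats:
    p = np.asarray(pixels, dtype=float).ravel()
    if p.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    return RoiStats(mean=float(p.mean()), sd=float(p.std(ddof=1)),
                    ntd=ntd(p), n=int(p.size))


def cnr(mu1: float, mu2: float, sigma: float) -> float:
    """Contrast-to-noise ratio (mu1 - mu2) / sigma.

    mu1 = homogeneous-insert mean, mu2 = background mean, sigma = insert SD.
    """
    if sigma <= 0:
        raise ValueError("CNR undefined for sigma <= 0")
    return (mu1 - mu2) / sigma


def homogeneity(roi_means) -> float:
    """Max difference among the insert ROIs' mean CT numbers (HU)."""
    means = np.asarray(list(roi_means), dtype=float)
    if means.size < 2:
        raise ValueError("homogeneity needs at least 2 ROI means")
    return float(means.max() - means.min())


def compare_groups(values_a, values_b, alpha: float = 0.05) -> dict:
    """Welch two-sample t-test between two groups of per-slice metric values."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "significant": False}
        return {"t": math.copysign(math.inf, a.mean() - b.mean()), "p": 0.0,
                "significant": True}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha)}


# ---------------------------------------------------------------------------
# Per-slice measurement and aggregation
# ---------------------------------------------------------------------------


def measure_stack(stack: ImageStack, rois: RoiSet,
                  ntd_rois: str = "insert") -> pd.DataFrame:
    """One row of noise / CNR / NTD / homogeneity per slice of a stack.

    ``ntd_rois`` selects which ROIs enter the per-slice NTD average:
    "insert" (central + peripheral, the default) or "central".
    """
    if ntd_rois not in ("insert", "central"):
        raise ValueError("ntd_rois must be 'insert' or 'central'")
    rows = []
    for k in range(stack.n_slices):
        img = stack.voxels[k]
        central = roi_stats(extract_roi(img, rois.central))
        background = roi_stats(extract_roi(img, rois.background))
        insert_stats = [central] + [roi_stats(extract_roi(img, r))
                                    for r in rois.peripheral]
        if ntd_rois == "insert":
            ntd_val = float(np.mean([s.ntd for s in insert_stats]))
        else:
            ntd_val = central.ntd
        rows.append({
            "scan_id": stack.scan_id,
            "algorithm": stack.algorithm,
            "dose_ctdi": stack.dose_ctdi,
            "slice_thickness": stack.slice_thickness,
            "slice": k,
            "insert_mean": central.mean,
            "background_mean": background.mean,
            "noise": central.sd,
            "cnr": cnr(central.mean, background.mean, central.sd)
                   if central.sd > 0 else np.nan,
            "ntd": ntd_val,
            "homogeneity": homogeneity([s.mean for s in insert_stats]),
        })
    return pd.DataFrame(rows)


def aggregate(per_slice: pd.DataFrame, baseline: str,
              baseline_thickness: float | None = None) -> pd.DataFrame:
    """Condition-level means/SDs with relative CNR against a baseline.

    Groups per-slice rows by (algorithm, dose, thickness), pooling all
    slices of all repeat scans in a cell, and computes relative CNR against
    the named baseline algorithm within the same dose level (the baseline
    thickness may differ, e.g. thin-slice arms compared to 2.5 mm FBP).
    """
    keys = ["algorithm", "dose_ctdi", "slice_thickness"]
    grouped = per_slice.groupby(keys, sort=True)
    out = grouped.agg(
        noise_mean=("noise", "mean"), noise_sd=("noise", "std"),
        cnr_mean=("cnr", "mean"), cnr_sd=("cnr", "std"),
        ntd_mean=("ntd", "mean"), ntd_sd=("ntd", "std"),
        homogeneity_min=("homogeneity", "min"),
        homogeneity_max=("homogeneity", "max"),
        n_slices=("noise", "size"),
    ).reset_index()
    out[["noise_sd", "cnr_sd", "ntd_sd"]] = (
        out[["noise_sd", "cnr_sd", "ntd_sd"]].fillna(0.0))

    base = out[out["algorithm"] == baseline]
    if baseline_thickness is not None:
        base = base[base["slice_thickness"] == baseline_thickness]
    base_by_dose = {}
    for _, row in base.iterrows():
        if row["dose_ctdi"] in base_by_dose:
            raise ValueError(
                f"baseline {baseline!r} ambiguous at dose {row['dose_ctdi']}: "
                "multiple slice thicknesses; pass baseline_thickness")
        base_by_dose[row["dose_ctdi"]] = row["cnr_mean"]

    def rel(row):
        dose = row["dose_ctdi"]
        if dose not in base_by_dose:
            raise ValueError(
                f"baseline {baseline!r} missing for dose level {dose}")
        return row["cnr_mean"] / base_by_dose[dose]

    out["relative_cnr"] = out.apply(rel, axis=1)
    return out
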