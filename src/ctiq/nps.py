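"""Noise power spectrum estimation from homogeneous-insert ROIs.

The 2D NPS is estimated from square ROIs extracted from the homogeneous
insert on every analyzed slice:

    NPS(u, v) = (dx * dy) / (Nx * Ny) * < |DFT(detrended ROI)|^2 >

averaged over all ROIs of all slices of one scan, then radially averaged to a
1D profile on bins of width 1/(w * dx) up to the Nyquist frequency. Profiles
of repeat scans at one condition are averaged arithmetically and normalized
by total noise power (nNPS integrates to one). The scalar texture summary is
the power-weighted mean frequency

    f_avg = sum(f * NPS(f)) / sum(NPS(f))

over the 1D bins — lower f_avg means coarser, smoother noise texture.

Detrending is needed on anthropomorphic backgrounds whose low-order HU
gradients would otherwise leak into the low-frequency bins; the default
removes a first-order polynomial surface per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ImageStack, PhantomLayout
from .roi import Roi, extract_roi

# ---------------------------------------------------------------------------
# ROI placement for NPS
# ---------------------------------------------------------------------------


def nps_roi_layout(layout: PhantomLayout, roi_size: int = 32) -> tuple[Roi, ...]:
    """Four square ROIs in quadrant arrangement fully inside the insert."""
    s = layout.pixel_spacing
    ny, nx = layout.grid_size
    cc = int(round(layout.insert_center_mm[0] / s + nx / 2.0 - 0.5))
    cr = int(round(layout.insert_center_mm[1] / s + ny / 2.0 - 0.5))
    r_px = layout.insert_diameter_mm / 2.0 / s
    half = roi_size / 2.0
    off = int(np.floor(r_px / np.sqrt(2.0) - half))
    if off < 1:
        raise ValueError(f"insert too small for {roi_size}x{roi_size} NPS ROIs")
    out = []
    for dr, dc in ((-off, -off), (-off, off), (off, -off), (off, off)):
        out.append(Roi(cr + dr - roi_size // 2, cc + dc - roi_size // 2,
                       roi_size, roi_size))
    return tuple(out)


def extract_nps_rois(stack: ImageStack, rois) -> list[np.ndarray]:
    """All ROI blocks from all slices of a stack, as a flat list."""
    return [extract_roi(stack.voxels[k], r)
            for k in range(stack.n_slices) for r in rois]


# ---------------------------------------------------------------------------
# Spectrum estimation
# ---------------------------------------------------------------------------


def _detrend(block: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return block - 0.0
    if method == "mean":
        return block - block.mean()
    if method == "poly1":
        ny, nx = block.shape
        y, x = np.mgrid[0:ny, 0:nx]
        a = np.column_stack([np.ones(block.size), x.ravel(), y.ravel()])
        coef, *_ = np.linalg.lstsq(a, block.ravel(), rcond=None)
        return block - (a @ coef).reshape(block.shape)
    raise ValueError(f"unknown detrend method {method!r}")


def nps_2d(rois: list[np.ndarray], spacing: float,
           detrend: str = "poly1") -> np.ndarray:
    """Ensemble-averaged 2D NPS (HU^2 mm^2) of square ROI blocks.

    Frequencies are laid out as by ``numpy.fft.fftfreq`` (DC in the corner).
    """
    if len(rois) < 4:
        raise ValueError("NPS estimation needs at least 4 ROIs")
    shape = np.asarray(rois[0]).shape
    if shape[0] != shape[1]:
        raise ValueError("NPS ROIs must be square")
    acc = np.zeros(shape)
    for block in rois:
        block = np.asarray(block, dtype=float)
        if block.shape != shape:
            raise ValueError("all NPS ROIs must have the same size")
        d = _detrend(block, detrend)
        acc += np.abs(np.fft.fft2(d)) ** 2
    n = shape[0]
    return acc / len(rois) * spacing ** 2 / (n * n)


def radial_average(nps2d: np.ndarray, spacing: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Radial average of a 2D NPS onto 1D bins of width 1/(w*dx).

    Bin k is centered at k * df; 2D samples are assigned to the nearest bin
    by radius; bins beyond Nyquist or with no contributing samples are
    dropped. Returns (freq_axis, nps1d).
    """
    n = nps2d.shape[0]
    if nps2d.ndim != 2 or nps2d.shape[1] != n:
        raise ValueError("2D NPS must be square")
    f = np.fft.fftfreq(n, d=spacing)
    fr = np.hypot(*np.meshgrid(f, f))
    df = 1.0 / (n * spacing)
    nyq = 1.0 / (2.0 * spacing)
    idx = np.round(fr / df).astype(int).ravel()
    vals = nps2d.ravel()
    n_bins = int(np.floor(nyq / df)) + 1
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=vals[keep], minlength=n_bins)
    nonempty = counts > 0
    freq = np.arange(n_bins)[nonempty] * df
    return freq, sums[nonempty] / counts[nonempty]


@dataclass(frozen=True)
class NpsResult:
    freq_axis: np.ndarray  # mm^-1
    nps1d: np.ndarray  # HU^2 mm^2
    nnps1d: np.ndarray  # normalized: sum(nnps * df) == 1
    total_power: float  # HU^2, from the 2D spectrum (Parseval)
    f_avg: float  # mm^-1
    n_rois: int
    detrend: str


def f_avg(freq_axis: np.ndarray, nps1d: np.ndarray) -> float:
    """Power-weighted mean spatial frequency of a 1D NPS."""
    f = np.asarray(freq_axis, dtype=float)
    p = np.asarray(nps1d, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("f_avg undefined for an all-zero spectrum")
    return float((f * p).sum() / total)


def scan_nps(rois: list[np.ndarray], spacing: float, detrend: str = "poly1"
             ) -> dict:
    """Per-scan NPS: 2D estimate, its radial profile, and total power."""
    spec2d = nps_2d(rois, spacing, detrend)
    freq, prof = radial_average(spec2d, spacing)
    n = spec2d.shape[0]
    df2 = (1.0 / (n * spacing)) ** 2
    return {"freq": freq, "nps1d": prof,
            "total_power": float(spec2d.sum() * df2),
            "n_rois": len(rois), "detrend": detrend}


def normalize_and_average(scans: list[dict]) -> NpsResult:
    """Average 1D NPS across repeat scans, then normalize by total power.

    Averaging precedes normalization; normalization divides by the integral
    of the averaged profile so the nNPS integrates to one over frequency.
    """
    if not scans:
        raise ValueError("need at least one scan")
    freq = scans[0]["freq"]
    for s in scans[1:]:
        if len(s["freq"]) != len(freq) or not np.allclose(s["freq"], freq):
            raise ValueError("scans have mismatched frequency axes")
    mean_nps = np.mean([s["nps1d"] for s in scans], axis=0)
    df = freq[1] - freq[0] if len(freq) > 1 else 1.0
    power_1d = mean_nps.sum() * df
    if power_1d <= 0:
        raise ValueError("zero total noise power; cannot normalize")
    return NpsResult(
        freq_axis=freq, nps1d=mean_nps, nnps1d=mean_nps / power_1d,
        total_power=float(np.mean([s["total_power"] for s in scans])),
        f_avg=f_avg(freq, mean_nps),
        n_rois=int(sum(s["n_rois"] for s in scans)),
        detrend=scans[0]["detrend"])
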