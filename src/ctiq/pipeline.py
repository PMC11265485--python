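"""End-to-end orchestration: simulate -> measure -> compare -> model.

A run is driven by a single :class:`RunConfig` (loadable from YAML) naming
exactly one input source — a simulation design, a raw-fixture directory, or a
DICOM directory — plus the analysis settings. The output is a
:class:`ReportBundle` of tidy tables: per-slice ROI metrics, condition-level
aggregates with relative CNR, per-condition radial NPS with f_avg (and percent
difference from the baseline algorithm), TTF f50 at the highest dose level,
and the noise-based dose-reduction estimates with delta-method CIs.

All randomness derives from the single master seed: scan k (in the sorted
condition order) uses seed ``SeedSequence([master, k])``, so results are
independent of execution order and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import (ImageStack, NoiseModel, NpsShape, Blotch, PhantomLayout,
                      read_dicom_series, read_fixture, reference_noise_models,
                      simulate_scan, write_fixture)
from .roi import aggregate, default_roi_layout, measure_stack
from .nps import extract_nps_rois, normalize_and_average, nps_roi_layout, scan_nps
from .ttf import measure_ttf, ttf_average
from .dose import dose_reduction, fit_noise_dose

log = logging.getLogger("ctiq")

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimDesign:
    """Simulation design: which arms to synthesize.

    ``algorithms`` maps label -> noise-model keyword dict (see NoiseModel);
    the string "reference" expands to the seven built-in FBP/IR/DLR-like
    models. The full study analogue is 7 algorithms x 5 doses x 3 repeats.
    """

    algorithms: dict | str = "reference"
    doses: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    repeats: int = 3
    n_slices: int = 40
    thicknesses: tuple[float, ...] = (2.5,)
    sigma_fbp: float = 10.0

    def noise_models(self, layout: PhantomLayout) -> dict[str, NoiseModel]:
        if self.algorithms == "reference":
            return reference_noise_models(layout, sigma_fbp=self.sigma_fbp)
        models = {}
        for label, kw in self.algorithms.items():
            kw = dict(kw)
            if "nps_shape" in kw and isinstance(kw["nps_shape"], dict):
                kw["nps_shape"] = NpsShape(**kw["nps_shape"])
            if "blotch" in kw and isinstance(kw["blotch"], dict):
                kw["blotch"] = Blotch(**kw["blotch"])
            models[label] = NoiseModel(label=label, **kw)
        return models

    def conditions(self) -> list[tuple[str, float, float, int]]:
        """Sorted (algorithm, dose, thickness, repeat) tuples."""
        algs = (sorted(self.algorithms) if isinstance(self.algorithms, dict)
                else sorted(reference_noise_models()))
        return [(a, d, t, r)
                for a in algs
                for d in sorted(self.doses)
                for t in sorted(self.thicknesses)
                for r in range(self.repeats)]


@dataclass
class RunConfig:
    source: str = "simulate"  # "simulate" | "fixtures" | "dicom"
    input_dir: str | None = None
    design: SimDesign = field(default_factory=SimDesign)
    layout: PhantomLayout = field(default_factory=PhantomLayout)
    baseline: str = "FBP"
    reference: str = "IR50"  # dose-model reference algorithm
    d_ref: float = 25.0
    ntd_rois: str = "insert"
    nps_detrend: str = "poly1"
    nps_roi_size: int = 32
    ttf_r_max_factor: float = 1.8
    ttf_monotone: bool = True
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.source not in ("simulate", "fixtures", "dicom"):
            raise ValueError("source must be simulate, fixtures, or dicom")
        if self.source != "simulate" and not self.input_dir:
            raise ValueError(f"source {self.source!r} requires input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "design" in raw:
            d = dict(raw["design"])
            for key in ("doses", "thicknesses"):
                if key in d:
                    d[key] = tuple(d[key])
            raw["design"] = SimDesign(**d)
        if "layout" in raw:
            la = dict(raw["layout"])
            for key in ("grid_size", "body_semiaxes_mm", "insert_center_mm",
                        "lc_center_mm"):
                if key in la:
                    la[key] = tuple(la[key])
            raw["layout"] = PhantomLayout(**la)
        return cls(**raw)

    def digest(self) -> str:
        def default(o):
            return repr(o)
        payload = json.dumps(self.__dict__, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Input validation / manifest
# ---------------------------------------------------------------------------


def validate_inputs(directory: str | Path) -> pd.DataFrame:
    """Manifest of fixture and DICOM stacks found under a directory.

    Rejects mixed pixel spacings within one (algorithm, dose, thickness)
    analysis group, naming the offending scans.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    rows = []
    for sidecar in sorted(directory.glob("*.json")):
        meta = json.loads(sidecar.read_text())
        if "shape" not in meta:
            continue
        rows.append({"scan_id": meta.get("scan_id", sidecar.stem),
                     "format": "fixture", "algorithm": meta["algorithm"],
                     "dose_ctdi": meta["dose_ctdi"],
                     "slice_thickness": meta["slice_thickness"],
                     "pixel_spacing": meta["pixel_spacing"],
                     "n_slices": meta["shape"][0], "path": str(sidecar)})
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        if not any(sub.glob("*.dcm")):
            continue
        stack = read_dicom_series(sub)
        rows.append({"scan_id": stack.scan_id, "format": "dicom",
                     "algorithm": stack.algorithm,
                     "dose_ctdi": stack.dose_ctdi,
                     "slice_thickness": stack.slice_thickness,
                     "pixel_spacing": stack.pixel_spacing,
                     "n_slices": stack.n_slices, "path": str(sub)})
    manifest = pd.DataFrame(rows, columns=[
        "scan_id", "format", "algorithm", "dose_ctdi", "slice_thickness",
        "pixel_spacing", "n_slices", "path"])
    if manifest.empty:
        warnings.warn(f"no input stacks found under {directory}")
        return manifest
    for key, grp in manifest.groupby(["algorithm", "dose_ctdi",
                                      "slice_thickness"]):
        spacings = grp["pixel_spacing"].unique()
        if len(spacings) > 1:
            ids = ", ".join(grp["scan_id"])
            raise ValueError(
                f"mixed pixel spacings {sorted(spacings)} within analysis "
                f"group {key}: scans {ids}")
    return manifest


def _load_stack(row: pd.Series) -> ImageStack:
    if row["format"] == "fixture":
        return read_fixture(row["path"])
    return read_dicom_series(row["path"])


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    per_slice: pd.DataFrame
    metrics: pd.DataFrame  # condition-level aggregates + relative CNR
    nps_table: pd.DataFrame  # per condition: f_avg + % vs baseline
    nps_curves: pd.DataFrame  # long-form (condition, f, NPS, nNPS)
    ttf_table: pd.DataFrame  # per algorithm at top dose: f50 + % vs baseline
    ttf_curves: pd.DataFrame
    dose_table: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_slice.to_csv(out / "per_slice_metrics.csv", index=False)
        self.metrics.to_csv(out / "aggregate_metrics.csv", index=False)
        self.nps_table.to_csv(out / "nps_summary.csv", index=False)
        self.nps_curves.to_csv(out / "nps_curves.csv", index=False)
        self.ttf_table.to_csv(out / "ttf_summary.csv", index=False)
        self.ttf_curves.to_csv(out / "ttf_curves.csv", index=False)
        self.dose_table.to_csv(out / "dose_reduction.csv", index=False)
        (out / "summary.json").write_text(json.dumps({
            "provenance": self.provenance,
            "nps_f_avg": self.nps_table.to_dict(orient="records"),
            "ttf_f50": self.ttf_table.to_dict(orient="records"),
            "dose_reduction": self.dose_table.to_dict(orient="records"),
        }, indent=1, default=float))
        return out


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


def _scan_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0]
               & 0x7FFFFFFF)


def _iter_stacks(config: RunConfig):
    """Yield ImageStacks one at a time (simulated or loaded)."""
    if config.source == "simulate":
        layout = config.layout
        models = config.design.noise_models(layout)
        for idx, (alg, dose, thick, rep) in enumerate(config.design.conditions()):
            seed = _scan_seed(config.seed, idx)
            scan_id = f"{alg}_d{dose:g}_t{thick:g}_r{rep}"
            yield simulate_scan(layout, models[alg], dose, thick,
                                config.design.n_slices, seed, scan_id)
    else:
        manifest = validate_inputs(config.input_dir)
        for _, row in manifest.iterrows():
            yield _load_stack(row)


def run(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline and (optionally) write the report tables."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    layout = config.layout
    rois = default_roi_layout(layout)
    nps_rois = nps_roi_layout(layout, config.nps_roi_size)

    per_slice_frames = []
    nps_per_scan: dict[tuple, list] = {}
    ttf_per_scan: dict[tuple, list] = {}
    n_scans = 0
    if config.source == "simulate":
        max_dose = max(config.design.doses)
    else:
        max_dose = float(validate_inputs(config.input_dir)["dose_ctdi"].max())

    for stack in _iter_stacks(config):
        key = (stack.algorithm, stack.dose_ctdi, stack.slice_thickness)
        try:
            per_slice_frames.append(
                measure_stack(stack, rois, ntd_rois=config.ntd_rois))
        except Exception as e:
            raise RuntimeError(
                f"stage roi_metrics failed for scan {stack.scan_id}") from e
        try:
            nps_per_scan.setdefault(key, []).append(
                scan_nps(extract_nps_rois(stack, nps_rois),
                         stack.pixel_spacing, config.nps_detrend))
        except Exception as e:
            raise RuntimeError(
                f"stage nps_analysis failed for scan {stack.scan_id}") from e
        if stack.dose_ctdi == max_dose:
            try:
                ttf_per_scan.setdefault(key, []).append(
                    measure_ttf(stack, layout,
                                r_max_factor=config.ttf_r_max_factor,
                                monotone=config.ttf_monotone))
            except Exception as e:
                raise RuntimeError(
                    f"stage ttf_analysis failed for scan {stack.scan_id}") from e
        n_scans += 1
        log.info("measured scan %s (%d slices)", stack.scan_id, stack.n_slices)

    if not per_slice_frames:
        raise ValueError("no input stacks")
    per_slice = pd.concat(per_slice_frames, ignore_index=True)
    if config.baseline not in set(per_slice["algorithm"]):
        raise ValueError(f"baseline algorithm {config.baseline!r} not present "
                         f"in the data")

    metrics = aggregate(per_slice, config.baseline)

    # --- NPS summary -------------------------------------------------------
    nps_rows, curve_rows = [], []
    nps_results = {key: normalize_and_average(scans)
                   for key, scans in sorted(nps_per_scan.items())}
    base_favg = {(dose, th): r.f_avg for (alg, dose, th), r in
                 nps_results.items() if alg == config.baseline}
    for (alg, dose, th), r in nps_results.items():
        base = base_favg.get((dose, th))
        nps_rows.append({
            "algorithm": alg, "dose_ctdi": dose, "slice_thickness": th,
            "f_avg": r.f_avg, "total_power": r.total_power,
            "pct_vs_baseline": (100.0 * (r.f_avg - base) / base
                                if base else np.nan)})
        for f, p, np_ in zip(r.freq_axis, r.nps1d, r.nnps1d):
            curve_rows.append({"algorithm": alg, "dose_ctdi": dose,
                               "slice_thickness": th, "freq": f,
                               "nps": p, "nnps": np_})
    nps_table = pd.DataFrame(nps_rows)
    nps_curves = pd.DataFrame(curve_rows)

    # --- TTF summary (highest dose level only, by default) -----------------
    ttf_rows, ttf_curve_rows = [], []
    ttf_results = {key: ttf_average(scans)
                   for key, scans in sorted(ttf_per_scan.items())}
    base_f50 = {(dose, th): r.f50 for (alg, dose, th), r in
                ttf_results.items() if alg == config.baseline}
    for (alg, dose, th), r in ttf_results.items():
        base = base_f50.get((dose, th))
        ttf_rows.append({
            "algorithm": alg, "dose_ctdi": dose, "slice_thickness": th,
            "f50": r.f50, "contrast": r.contrast,
            "pct_vs_baseline": (100.0 * (r.f50 - base) / base
                                if base and r.f50 is not None else np.nan)})
        for f, t in zip(r.freq_axis, r.ttf):
            ttf_curve_rows.append({"algorithm": alg, "dose_ctdi": dose,
                                   "slice_thickness": th, "freq": f, "ttf": t})
    ttf_table = pd.DataFrame(ttf_rows)
    ttf_curves = pd.DataFrame(ttf_curve_rows)

    # --- Dose-reduction model ---------------------------------------------
    scan_noise = (per_slice.groupby(
        ["algorithm", "slice_thickness", "dose_ctdi", "scan_id"])["noise"]
        .mean().reset_index())
    fits = {}
    for (alg, th), grp in scan_noise.groupby(["algorithm", "slice_thickness"]):
        if grp["dose_ctdi"].nunique() < 2 or len(grp) < 3:
            continue
        fits[(alg, th)] = fit_noise_dose(
            grp[["dose_ctdi", "noise"]].to_numpy(), algorithm=alg)
    ref_fits = {th: f for (alg, th), f in fits.items()
                if alg == config.reference}
    if not ref_fits:
        raise ValueError(
            f"dose-model reference algorithm {config.reference!r} has no "
            f"fit (needs >= 3 scans over >= 2 dose levels)")
    ref_fit = next(iter(sorted(ref_fits.items())))[1]
    dose_rows = []
    for (alg, th), fit in sorted(fits.items()):
        if alg == config.reference:
            continue
        est = dose_reduction(fit, ref_fit, config.d_ref)
        dose_rows.append({
            "test": alg, "slice_thickness": th, "reference": config.reference,
            "d_ref": est.d_ref, "d_equiv": est.d_equiv, "delta": est.delta,
            "percent": est.percent, "percent_rounded": round(est.percent),
            "ci_low": est.ci95[0], "ci_high": est.ci95[1], "p": est.p})
    dose_table = pd.DataFrame(dose_rows, columns=[
        "test", "slice_thickness", "reference", "d_ref", "d_equiv", "delta",
        "percent", "percent_rounded", "ci_low", "ci_high", "p"])

    n_images = int(len(per_slice))
    log.info("analyzed %d scans / %d CT images in %.1f s",
             n_scans, n_images, time.time() - t0)
    bundle = ReportBundle(
        per_slice=per_slice, metrics=metrics, nps_table=nps_table,
        nps_curves=nps_curves, ttf_table=ttf_table, ttf_curves=ttf_curves,
        dose_table=dose_table,
        provenance={"config_digest": config.digest(), "seed": config.seed,
                    "ctiq_version": __version__, "n_scans": n_scans,
                    "n_images": n_images})
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def simulate_to_dir(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Materialize the simulation design as raw+JSON fixtures on disk."""
    if config.source != "simulate":
        raise ValueError("simulate_to_dir requires a simulate-source config")
    paths = []
    for stack in _iter_stacks(config):
        paths.append(write_fixture(stack, out_dir))
    return paths
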