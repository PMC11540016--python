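"""End-to-end dosimetric verification workflow.

``run_verify`` chains the full gel-readout QA sequence: average the
pre-/post-irradiation scans, subtract the background, filter, remove
remnant artifacts, self-calibrate on the slice spanning the widest plan
dose range, invert to a 3D gel dose volume, and compare it against the
plan (per-vertex equivalent diameters, valley metrics along an
inter-vertex profile, and the 12-criterion gamma sweep). The pipeline is
a pure function of (inputs, config): repeated runs produce identical
reports.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from . import __version__
from .analysis import (
    compare_vertex_reports,
    equivalent_diameters,
    gamma_sweep,
    line_profile,
    sweep_table,
    valley_metrics,
)
from .io import read_mask, read_volume, write_volume
from .lattice import LatticeSpec, VertexSet, build_lattice
from .readout import (
    FilterConfig,
    adaptive_mean_filter,
    apply_calibration,
    fit_calibration,
    remove_remnant_artifacts,
    tanh_response,
)
from .volumes import Quantity, ScalarVolume, StructureMask, average_volumes, subtract_background

logger = logging.getLogger("gelattice")

__all__ = ["RunConfig", "run_verify", "readout_chain", "PipelineError"]


class PipelineError(RuntimeError):
    """A verify stage failed; the message names the stage and file."""


@dataclass
class RunConfig:
    """Configuration of one verification run (paths and parameters)."""

    plan_dose: str
    pre_scans: list[str]
    post_scans: list[str]
    gel_mask: str
    target_mask: Optional[str] = None
    vertices: Optional[str] = None  # JSON from the lattice tool
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    anchor: str | Sequence[float] = "centroid"
    filter: FilterConfig = field(default_factory=FilterConfig)
    calibration_slice: str | int = "auto"
    prescription_gy: float = 20.0
    dose_percents: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0)
    dta_mms: tuple[float, ...] = (1.0, 2.0, 3.0)
    threshold_percent: float = 10.0
    gamma_refinement: int = 3
    axis_center: tuple[float, float] = (0.0, 0.0)
    erode_margin_voxels: int = 2
    output_dir: str = "verify_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be > 0")
        if self.vertices is None and self.target_mask is None:
            raise ValueError("either vertices or target_mask must be given")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        lat = raw.pop("lattice", {}) or {}
        filt = raw.pop("filter", {}) or {}
        gamma = raw.pop("gamma", {}) or {}
        kwargs = dict(raw)
        kwargs["lattice"] = LatticeSpec(
            pattern=lat.get("pattern", "hexagonal"),
            sphere_diameter=lat.get("sphere_diameter_mm", 15.0),
            spacing=lat.get("spacing_mm", 30.0),
            shift_x=lat.get("shift_x_mm", 0.0),
            shift_y=lat.get("shift_y_mm", 0.0),
        )
        kwargs["anchor"] = lat.get("anchor", "centroid")
        kwargs["filter"] = FilterConfig(
            mean_window=filt.get("mean_window", 3),
            artefact_span=filt.get("artefact_span", 7),
            baseline_span=filt.get("baseline_span", None),
        )
        kwargs["dose_percents"] = tuple(gamma.get("dose_percents", (1.0, 2.0, 3.0, 5.0)))
        kwargs["dta_mms"] = tuple(gamma.get("dta_mms", (1.0, 2.0, 3.0)))
        kwargs["threshold_percent"] = gamma.get("threshold_percent", 10.0)
        kwargs["gamma_refinement"] = gamma.get("refinement", 3)
        if "axis_center" in kwargs:
            kwargs["axis_center"] = tuple(kwargs["axis_center"])
        return cls(**kwargs)

    def echo(self) -> dict:
        return {
            "plan_dose": self.plan_dose,
            "pre_scans": list(self.pre_scans),
            "post_scans": list(self.post_scans),
            "gel_mask": self.gel_mask,
            "target_mask": self.target_mask,
            "vertices": self.vertices,
            "lattice": {
                "pattern": self.lattice.pattern,
                "sphere_diameter_mm": self.lattice.sphere_diameter,
                "spacing_mm": self.lattice.spacing,
                "shift_x_mm": self.lattice.shift_x,
                "shift_y_mm": self.lattice.shift_y,
                "anchor": self.anchor if isinstance(self.anchor, str) else list(self.anchor),
            },
            "filter": {
                "mean_window": self.filter.mean_window,
                "artefact_span": self.filter.artefact_span,
                "baseline_span": self.filter.baseline_span,
            },
            "calibration_slice": self.calibration_slice,
            "prescription_gy": self.prescription_gy,
            "gamma": {
                "dose_percents": list(self.dose_percents),
                "dta_mms": list(self.dta_mms),
                "threshold_percent": self.threshold_percent,
                "refinement": self.gamma_refinement,
            },
            "axis_center": list(self.axis_center),
            "erode_margin_voxels": self.erode_margin_voxels,
            "seed": self.seed,
        }


def _check_inputs(config: RunConfig) -> None:
    paths = [config.plan_dose, config.gel_mask, *config.pre_scans, *config.post_scans]
    if config.target_mask:
        paths.append(config.target_mask)
    if config.vertices:
        paths.append(config.vertices)
    for p in paths:
        if not os.path.exists(p):
            raise PipelineError(f"stage 'inputs': missing file '{p}'")


def _eroded(mask_values: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0:
        return mask_values
    return ndimage.binary_erosion(mask_values, iterations=margin)


def _auto_calibration_slice(plan_values: np.ndarray, region: np.ndarray) -> int:
    """Slice index (z) with the widest in-region plan dose range."""
    best_k, best_span = 0, -1.0
    for k in range(plan_values.shape[2]):
        sel = region[:, :, k]
        if sel.sum() < 16:
            continue
        vals = plan_values[:, :, k][sel]
        span = float(vals.max() - vals.min())
        if span > best_span:
            best_k, best_span = k, span
    if best_span <= 0:
        raise PipelineError("stage 'calibrate': no slice with a usable dose range")
    return best_k


def readout_chain(
    pre_scans: Sequence[ScalarVolume],
    post_scans: Sequence[ScalarVolume],
    plan: ScalarVolume,
    gel_mask: StructureMask,
    filter_cfg: FilterConfig = FilterConfig(),
    axis_center: tuple[float, float] = (0.0, 0.0),
    calibration_slice: str | int = "auto",
    erode_margin_voxels: int = 2,
):
    """In-memory gel readout: scans to calibrated 3D dose.

    Averages the scan groups, subtracts the background, applies the
    adaptive mean filter, removes remnant artifacts, self-calibrates
    against the plan and inverts the curve. Calibration is two-pass: a
    first-pass fit on the filtered image predicts the expected response,
    the remnant is estimated on the residual (so the phantom's own
    azimuthally symmetric dose structure is not mistaken for artifact),
    and the curve is refitted on the cleaned image.

    Returns ``(gel_dose, curve, info)`` with ``info`` carrying the
    calibration slice index and clamping statistics.
    """
    delta = subtract_background(average_volumes(post_scans), average_volumes(pre_scans))
    delta = adaptive_mean_filter(delta, window=filter_cfg.mean_window)
    fit_region = _eroded(gel_mask.values, erode_margin_voxels)
    if calibration_slice == "auto":
        k_cal = _auto_calibration_slice(plan.values, fit_region)
    else:
        k_cal = int(calibration_slice)
    curve0 = fit_calibration(
        delta.values[:, :, k_cal], plan.values[:, :, k_cal], mask=fit_region[:, :, k_cal]
    )
    model = np.where(gel_mask.values, tanh_response(plan.values, curve0), 0.0)
    delta = remove_remnant_artifacts(
        delta,
        span=filter_cfg.artefact_span,
        axis_center=axis_center,
        region=gel_mask.values,
        baseline_span=filter_cfg.baseline_span,
        exclude_model=model,
    )
    curve = fit_calibration(
        delta.values[:, :, k_cal], plan.values[:, :, k_cal], mask=fit_region[:, :, k_cal]
    )
    gel_dose, clamp_stats = apply_calibration(delta, curve, return_stats=True)
    info = {"calibration_slice": k_cal, "clamp_stats": clamp_stats}
    return gel_dose, curve, info


def _valley_profile_segment(vset: VertexSet) -> tuple[np.ndarray, np.ndarray]:
    """Segment through the central vertex and its nearest neighbour,
    extended by 40% of their separation on each side."""
    centers = vset.centers
    mid = centers.mean(axis=0)
    i = int(np.argmin(np.linalg.norm(centers - mid, axis=1)))
    d = np.linalg.norm(centers - centers[i], axis=1)
    d[i] = np.inf
    j = int(np.argmin(d))
    a, b = centers[i], centers[j]
    ext = 0.4 * (b - a)
    return a - ext, b + ext


def run_verify(config: RunConfig) -> dict:
    """Execute the full verification chain; returns the report dict and
    writes report.json plus CSV/NRRD artifacts into the output directory."""
    _check_inputs(config)
    os.makedirs(config.output_dir, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("read")
    plan = read_volume(config.plan_dose, quantity=Quantity.DOSE_GY)
    gel_mask = read_mask(config.gel_mask, name="gel")
    plan.geometry.require_compatible(gel_mask.geometry, what="plan vs gel mask")
    pre = [read_volume(p, quantity=Quantity.CBCT_NUMBER) for p in config.pre_scans]
    post = [read_volume(p, quantity=Quantity.CBCT_NUMBER) for p in config.post_scans]

    stage("vertices")
    if config.vertices:
        vset = VertexSet.from_json(config.vertices)
    else:
        target = read_mask(config.target_mask, name="GTV")
        vset = build_lattice(config.lattice, target, anchor=config.anchor)
    if len(vset) == 0:
        raise PipelineError("stage 'vertices': no lattice vertices inside the target")

    stage("readout")
    gel_dose, curve, info = readout_chain(
        pre,
        post,
        plan,
        gel_mask,
        filter_cfg=config.filter,
        axis_center=config.axis_center,
        calibration_slice=config.calibration_slice,
        erode_margin_voxels=config.erode_margin_voxels,
    )
    k_cal = info["calibration_slice"]
    clamp_stats = info["clamp_stats"]

    stage("report")
    rx = config.prescription_gy
    plan_report = equivalent_diameters(plan, rx, vset)
    gel_report = equivalent_diameters(gel_dose, rx, vset)
    vertex_table = compare_vertex_reports(plan_report, gel_report)

    start, end = _valley_profile_segment(vset)
    valley = None
    for shrink in (1.0, 0.6, 0.2):
        seg_start = start + (1 - shrink) * 0.5 * (end - start)
        seg_end = end - (1 - shrink) * 0.5 * (end - start)
        try:
            profile = line_profile(plan, gel_dose, seg_start, seg_end, step=min(plan.geometry.spacing))
            valley_ref = valley_metrics(
                profile, "volume_max", norm_dose=float(plan.values.max()), which="ref", rx=rx
            )
            valley_eval = valley_metrics(
                profile, "volume_max", norm_dose=float(gel_dose.values.max()), which="eval", rx=rx
            )
            valley = {
                "profile_start_mm": list(np.round(seg_start, 4)),
                "profile_end_mm": list(np.round(seg_end, 4)),
                "plan_min_valley_percent": valley_ref.min_valley_percent,
                "gel_min_valley_percent": valley_eval.min_valley_percent,
                "plan_peak_doses_Gy": list(np.round(valley_ref.peak_doses, 4)),
                "gel_peak_doses_Gy": list(np.round(valley_eval.peak_doses, 4)),
            }
            profile.to_csv(os.path.join(config.output_dir, "profile.csv"))
            break
        except ValueError:
            continue

    stage("gamma")
    gamma_region = _eroded(gel_mask.values, config.erode_margin_voxels)
    results = gamma_sweep(
        plan,
        gel_dose,
        dose_percents=config.dose_percents,
        dta_mms=config.dta_mms,
        threshold_percent=config.threshold_percent,
        refinement=config.gamma_refinement,
        region=gamma_region,
        keep_maps=False,
    )
    gamma_table = sweep_table(results)

    report = {
        "software_version": __version__,
        "config": config.echo(),
        "n_vertices": len(vset),
        "calibration": {
            "slice_index": k_cal,
            "alpha": curve.alpha,
            "beta": curve.beta,
            "gamma_": curve.gamma_,
            "phi": curve.phi,
            "rmse": curve.rmse,
            "dose_range_Gy": list(curve.dose_range),
            "ci95": {k: list(v) for k, v in curve.ci95().items()},
        },
        "clamp_stats": clamp_stats,
        "vertex_table": vertex_table,
        "vertex_summary": {
            "n_matched": len(gel_report.matched),
            "plan_mean_diameter_mm": plan_report.mean_diameter_mm,
            "plan_sd_diameter_mm": plan_report.sd_diameter_mm,
            "gel_mean_diameter_mm": gel_report.mean_diameter_mm,
            "gel_sd_diameter_mm": gel_report.sd_diameter_mm,
        },
        "valley": valley,
        "gamma_table": gamma_table,
    }

    stage("write")
    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    curve.to_json(
        os.path.join(config.output_dir, "calibration_curve.json"),
        extra={"software_version": __version__, "slice_index": k_cal},
    )
    write_volume(gel_dose, os.path.join(config.output_dir, "gel_dose.nrrd"))
    with open(os.path.join(config.output_dir, "gamma_table.csv"), "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["dose_percent", "dta_mm", "threshold_percent", "pass_percent", "evaluated_voxels"],
        )
        w.writeheader()
        w.writerows(gamma_table)
    with open(os.path.join(config.output_dir, "vertex_table.csv"), "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=[
                "label",
                "planned_center_mm",
                "plan_equivalent_diameter_mm",
                "gel_equivalent_diameter_mm",
                "normalized_difference",
            ],
        )
        w.writeheader()
        w.writerows(vertex_table)
    return report
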