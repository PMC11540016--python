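"""Dose-comparison suite: line profiles, peak/valley metrics, isodose
volumetrics with per-vertex equivalent diameters, and 3D global gamma
analysis.

Gamma analysis: for each reference voxel r above the low-dose threshold,

    gamma(r) = min_p sqrt( |p - r|^2 / dta^2
                           + (D_eval(p) - D_ref(r))^2 / (dD% * Dnorm / 100)^2 )

minimised over search points p on a sub-voxel grid (trilinear-interpolated
evaluated dose) inside a ball around r; a voxel passes when gamma <= 1.
"Global" means the dose tolerance is a percentage of a single
normalization dose (by default the reference maximum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .geometry import VolumeGeometry
from .lattice import VertexSet
from .volumes import Quantity, ScalarVolume, StructureMask

__all__ = [
    "Profile",
    "ValleyReport",
    "GammaCriteria",
    "GammaResult",
    "VertexReport",
    "line_profile",
    "valley_metrics",
    "isodose_mask",
    "equivalent_diameters",
    "compare_vertex_reports",
    "gamma_3d",
    "gamma_sweep",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------


@dataclass
class Profile:
    """Paired reference/evaluated dose samples along a world-space segment."""

    start: np.ndarray
    end: np.ndarray
    step: float
    positions: np.ndarray  # arc length, mm
    ref_values: np.ndarray
    eval_values: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        self.positions = np.asarray(self.positions, dtype=float)
        self.ref_values = np.asarray(self.ref_values, dtype=float)
        self.eval_values = np.asarray(self.eval_values, dtype=float)
        if not (len(self.positions) == len(self.ref_values) == len(self.eval_values)):
            raise ValueError("positions/ref/eval must have equal lengths")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def to_csv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["position_mm", "ref_Gy", "eval_Gy"])
            for p, r, e in zip(self.positions, self.ref_values, self.eval_values):
                w.writerow([f"{p:.4f}", f"{r:.6f}", f"{e:.6f}"])


def line_profile(
    ref: ScalarVolume,
    eval_: ScalarVolume,
    start: Sequence[float],
    end: Sequence[float],
    step: float = 0.5,
) -> Profile:
    """Trilinear samples of both volumes at uniform arc-length spacing."""
    ref.geometry.require_compatible(eval_.geometry, what="line_profile volumes")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if step <= 0:
        raise ValueError("step must be > 0")
    length = float(np.linalg.norm(end - start))
    if length <= 0:
        raise ValueError("start and end coincide")
    positions = np.arange(0.0, length + step / 2.0, step)
    direction = (end - start) / length
    points = start[None, :] + positions[:, None] * direction[None, :]
    ci = ref.geometry.world_to_continuous_index(points)
    upper = np.asarray(ref.geometry.dims) - 1
    bad = np.any((ci < -1e-9) | (ci > upper + 1e-9), axis=1)
    if np.any(bad):
        first = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"profile sample {first} at {points[first].tolist()} mm "
            f"(arc length {positions[first]:.2f} mm) is outside the volume extent"
        )
    coords = np.clip(ci, 0, upper).T
    ref_vals = ndimage.map_coordinates(ref.values, coords, order=1)
    eval_vals = ndimage.map_coordinates(eval_.values, coords, order=1)
    return Profile(start, end, step, positions, ref_vals, eval_vals)


# --------------------------------------------------------------------------
# valley metrics
# --------------------------------------------------------------------------


@dataclass
class ValleyReport:
    """Peaks, inter-peak valleys (as % of a normalization dose) and peak
    widths at the prescription level, for one sampled profile."""

    normalization: str
    norm_dose: float
    peak_positions_mm: np.ndarray
    peak_doses: np.ndarray
    valley_positions_mm: np.ndarray
    valley_doses: np.ndarray
    valley_percents: np.ndarray
    rx: Optional[float] = None
    peak_widths_at_rx_mm: Optional[np.ndarray] = None

    @property
    def min_valley_percent(self) -> float:
        return float(self.valley_percents.min())


def _width_at_level(positions: np.ndarray, values: np.ndarray, peak_i: int, level: float) -> float:
    """Full width of the peak at ``peak_i`` at the given dose level
    (linear interpolation to the crossings; NaN if a side never crosses)."""
    if values[peak_i] < level:
        return float("nan")

    def cross(idx_range) -> float:
        prev = peak_i
        for i in idx_range:
            if values[i] < level:
                # interpolate between i and prev
                f = (values[prev] - level) / (values[prev] - values[i])
                return positions[prev] + f * (positions[i] - positions[prev])
            prev = i
        return float("nan")

    left = cross(range(peak_i - 1, -1, -1))
    right = cross(range(peak_i + 1, len(values)))
    return float(right - left)


def valley_metrics(
    profile: Profile,
    normalization: str = "volume_max",
    norm_dose: Optional[float] = None,
    which: str = "eval",
    rx: Optional[float] = None,
    min_peak_separation_mm: float = 10.0,
    peak_height_frac: float = 0.5,
) -> ValleyReport:
    """Valley doses between adjacent profile peaks, as % of a normalization.

    Peaks are local maxima above ``peak_height_frac`` of the profile
    maximum separated by at least ``min_peak_separation_mm`` (half the
    lattice spacing by convention, to exclude noise peaks). For each pair
    of adjacent peaks the valley is the minimum between them. The
    normalization dose is the volume maximum (pass ``norm_dose``), the
    profile's own maximum, or the prescription dose (pass ``norm_dose``).
    When ``rx`` is given, each peak's full width at the prescription dose
    is also reported.
    """
    values = {"ref": profile.ref_values, "eval": profile.eval_values}[which]
    positions = profile.positions
    if normalization == "profile_max":
        norm = float(values.max())
    elif normalization in ("volume_max", "prescription"):
        if norm_dose is None:
            raise ValueError(f"normalization '{normalization}' requires norm_dose")
        norm = float(norm_dose)
    else:
        raise ValueError(f"unknown normalization '{normalization}'")
    if norm <= 0:
        raise ValueError("normalization dose must be > 0")
    distance = max(1, int(round(min_peak_separation_mm / profile.step)))
    peaks, _ = signal.find_peaks(
        values, height=peak_height_frac * float(values.max()), distance=distance
    )
    if len(peaks) < 2:
        raise ValueError(
            f"profile has {len(peaks)} peak(s) above {peak_height_frac:.0%} of its "
            "maximum; at least 2 are required to define a valley"
        )
    valley_pos, valley_dose = [], []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = values[a : b + 1]
        i = int(np.argmin(seg)) + a
        valley_pos.append(positions[i])
        valley_dose.append(values[i])
    widths = None
    if rx is not None:
        widths = np.array([_width_at_level(positions, values, p, rx) for p in peaks])
    valley_dose = np.asarray(valley_dose)
    return ValleyReport(
        normalization=normalization,
        norm_dose=norm,
        peak_positions_mm=positions[peaks],
        peak_doses=values[peaks],
        valley_positions_mm=np.asarray(valley_pos),
        valley_doses=valley_dose,
        valley_percents=100.0 * valley_dose / norm,
        rx=rx,
        peak_widths_at_rx_mm=widths,
    )


# --------------------------------------------------------------------------
# isodose volumetrics
# --------------------------------------------------------------------------


def isodose_mask(dose: ScalarVolume, level: float) -> StructureMask:
    """Voxels receiving at least ``level`` Gy."""
    if level <= 0:
        raise ValueError("isodose level must be > 0")
    return StructureMask(dose.geometry, dose.values >= level, name=f"isodose_{level:g}Gy")


def equivalent_diameter_mm(volume_mm3: float) -> float:
    """Diameter of the sphere with the same volume: ``(6 V / pi)^(1/3)``."""
    return float((6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0))


@dataclass
class VertexRow:
    label: int
    planned_center_mm: np.ndarray
    measured_centroid_mm: Optional[np.ndarray]
    volume_mm3: Optional[float]
    equivalent_diameter_mm: Optional[float]


@dataclass
class VertexReport:
    """Per-vertex isodose components and the summary over matched vertices."""

    level: float
    rows: list[VertexRow]

    @property
    def matched(self) -> list[VertexRow]:
        return [r for r in self.rows if r.equivalent_diameter_mm is not None]

    @property
    def mean_diameter_mm(self) -> float:
        d = [r.equivalent_diameter_mm for r in self.matched]
        return float(np.mean(d))

    @property
    def sd_diameter_mm(self) -> float:
        d = [r.equivalent_diameter_mm for r in self.matched]
        return float(np.std(d, ddof=1)) if len(d) > 1 else 0.0


def equivalent_diameters(
    dose: ScalarVolume,
    level: float,
    vset: VertexSet,
    max_match_distance: Optional[float] = None,
) -> VertexReport:
    """Equivalent diameter of each vertex's isodose component.

    Connected components (26-connectivity) of the ``level``-isodose mask
    are matched to planned vertex centers by nearest centroid within
    ``max_match_distance`` (default: half the minimum vertex spacing).
    Each matched component contributes ``d = (6 V / pi)^(1/3)`` with ``V``
    its volume in mm^3.
    """
    if len(vset) == 0:
        raise ValueError("vertex set is empty")
    if max_match_distance is None:
        mpd = vset.min_pairwise_distance()
        max_match_distance = vset.diameter if math.isinf(mpd) else mpd / 2.0
    mask = dose.values >= level
    labels, n_comp = ndimage.label(mask, structure=_CONN26)
    rows = [
        VertexRow(i + 1, c, None, None, None) for i, c in enumerate(vset.centers)
    ]
    if n_comp:
        counts = np.bincount(labels.ravel(), minlength=n_comp + 1)[1:]
        centroids_idx = ndimage.center_of_mass(mask, labels, index=np.arange(1, n_comp + 1))
        vox = dose.geometry.voxel_volume_mm3
        for comp, (cnt, cidx) in enumerate(zip(counts, centroids_idx), start=1):
            centroid = dose.geometry.index_to_world(np.asarray(cidx))
            dists = np.linalg.norm(vset.centers - centroid[None, :], axis=1)
            within = np.nonzero(dists <= max_match_distance)[0]
            if within.size > 1:
                raise ValueError(
                    f"isodose component {comp} at {centroid.tolist()} mm matches "
                    f"{within.size} vertices (labels {(within + 1).tolist()}); "
                    "this should be impossible while spacing >= diameter"
                )
            if within.size == 1:
                row = rows[int(within[0])]
                if row.volume_mm3 is not None:
                    raise ValueError(
                        f"two isodose components match vertex {row.label}"
                    )
                row.measured_centroid_mm = centroid
                row.volume_mm3 = float(cnt * vox)
                row.equivalent_diameter_mm = equivalent_diameter_mm(cnt * vox)
    return VertexReport(level=level, rows=rows)


def compare_vertex_reports(plan: VertexReport, gel: VertexReport) -> list[dict]:
    """Per-vertex table of plan vs gel equivalent diameters with the
    normalized difference ``|gel - plan| / plan``."""
    out = []
    for pr, gr in zip(plan.rows, gel.rows):
        entry = {
            "label": pr.label,
            "planned_center_mm": list(np.round(pr.planned_center_mm, 4)),
            "plan_equivalent_diameter_mm": pr.equivalent_diameter_mm,
            "gel_equivalent_diameter_mm": gr.equivalent_diameter_mm,
            "normalized_difference": None,
        }
        if pr.equivalent_diameter_mm and gr.equivalent_diameter_mm:
            entry["normalized_difference"] = (
                abs(gr.equivalent_diameter_mm - pr.equivalent_diameter_mm)
                / pr.equivalent_diameter_mm
            )
        out.append(entry)
    return out


# --------------------------------------------------------------------------
# gamma analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaCriteria:
    """One gamma criterion: dose difference (% of the normalization dose),
    distance-to-agreement (mm), and low-dose threshold (% of normalization)."""

    dose_percent: float
    dta_mm: float
    threshold_percent: float = 10.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0 or self.threshold_percent <= 0:
            raise ValueError("gamma criteria must be strictly positive")
        if self.threshold_percent >= 100:
            raise ValueError("threshold must be below 100% of the normalization dose")
        if self.mode != "global":
            raise ValueError("only global gamma is implemented")


@dataclass
class GammaResult:
    criteria: GammaCriteria
    gamma_map: Optional[ScalarVolume]  # 0 outside the evaluated region
    pass_percent: float
    evaluated_voxel_count: int
    evaluated_mask: Optional[np.ndarray] = None
    normalization_dose: float = 0.0


def _shift_trilinear(values: np.ndarray, offset_vox: np.ndarray) -> np.ndarray:
    """Sample ``values`` at every voxel index plus a constant fractional
    offset (trilinear); NaN where any interpolation corner falls outside."""
    b = np.floor(offset_vox).astype(int)
    f = offset_vox - b
    need_hi = [1 if f[a] > 1e-12 else 0 for a in range(3)]
    n = values.shape
    lo = [max(0, -b[a]) for a in range(3)]
    hi = [min(n[a], n[a] - b[a] - need_hi[a]) for a in range(3)]
    out = np.full(values.shape, np.nan)
    if any(hi[a] <= lo[a] for a in range(3)):
        return out
    shape = tuple(hi[a] - lo[a] for a in range(3))
    acc = np.zeros(shape)
    for cx in range(need_hi[0] + 1):
        wx = f[0] if cx else (1.0 - f[0])
        for cy in range(need_hi[1] + 1):
            wy = f[1] if cy else (1.0 - f[1])
            for cz in range(need_hi[2] + 1):
                wz = f[2] if cz else (1.0 - f[2])
                w = wx * wy * wz
                if w == 0.0:
                    continue
                src = tuple(
                    slice(lo[a] + b[a] + c, hi[a] + b[a] + c)
                    for a, c in zip(range(3), (cx, cy, cz))
                )
                acc += w * values[src]
    out[tuple(slice(lo[a], hi[a]) for a in range(3))] = acc
    return out


def _search_offsets(
    spacing: np.ndarray, dta: float, refinement: int, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-voxel displacement vectors (mm) within ``radius``, sorted by
    length; step = spacing / refinement on each axis. Returns (offsets,
    lengths)."""
    step = spacing / refinement
    nmax = np.floor(radius / step).astype(int)
    ax = [step[a] * np.arange(-nmax[a], nmax[a] + 1) for a in range(3)]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(grid, axis=1)
    keep = d <= radius + 1e-9
    grid, d = grid[keep], d[keep]
    order = np.argsort(d, kind="stable")
    return grid[order], d[order]


def gamma_3d(
    ref: ScalarVolume,
    eval_: ScalarVolume,
    criteria: GammaCriteria,
    refinement: int = 3,
    search_radius_factor: float = 3.0,
    norm_dose: Optional[float] = None,
    region: Optional[np.ndarray] = None,
    keep_map: bool = True,
) -> GammaResult:
    """3D global gamma of an evaluated dose volume against a reference.

    The normalization dose defaults to the reference maximum; voxels below
    ``criteria.threshold_percent`` of it (or outside ``region``) are not
    evaluated. The evaluated dose is sampled trilinearly on a sub-voxel
    displacement grid (``spacing / refinement``) inside a ball of radius
    ``search_radius_factor * dta``; displacements are visited in order of
    increasing length so a voxel is finalized exactly once the remaining
    spatial term alone exceeds its running gamma.
    """
    ref.geometry.require_compatible(eval_.geometry, what="gamma volumes")
    spacing = np.asarray(ref.geometry.spacing)
    dnorm = float(ref.values.max()) if norm_dose is None else float(norm_dose)
    if dnorm <= 0:
        raise ValueError("reference volume has no positive dose to normalize by")
    delta = criteria.dose_percent / 100.0 * dnorm
    dta = criteria.dta_mm
    evaluated = ref.values >= criteria.threshold_percent / 100.0 * dnorm
    if region is not None:
        evaluated &= np.asarray(region, dtype=bool)
    n_eval = int(evaluated.sum())
    geom = ref.geometry
    if n_eval == 0:
        gm = ScalarVolume(geom, np.zeros(geom.dims), Quantity.DIMENSIONLESS) if keep_map else None
        return GammaResult(criteria, gm, 100.0, 0, evaluated, dnorm)

    offsets, lengths = _search_offsets(spacing, dta, refinement, search_radius_factor * dta)
    ref_flat = ref.values[evaluated]
    gamma2 = np.full(n_eval, np.inf)
    active = np.arange(n_eval)
    flat_eval_idx = np.nonzero(evaluated.ravel())[0]
    vox_idx = np.array(np.unravel_index(flat_eval_idx, geom.dims), dtype=float)  # (3, n)
    gather_threshold = max(1024, n_eval // 20)

    i = 0
    n_off = len(offsets)
    while i < n_off and active.size:
        d_mm = lengths[i]
        # batch all offsets in the same distance shell
        j = i
        while j < n_off and lengths[j] <= d_mm + 1e-9:
            j += 1
        spatial2 = (d_mm / dta) ** 2
        for k in range(i, j):
            off_vox = offsets[k] / spacing
            if active.size > gather_threshold:
                shifted = _shift_trilinear(eval_.values, off_vox)
                vals = shifted.ravel()[flat_eval_idx[active]]
            else:
                coords = vox_idx[:, active] + off_vox[:, None]
                vals = ndimage.map_coordinates(
                    eval_.values, coords, order=1, mode="constant", cval=np.nan
                )
            cand = spatial2 + (vals - ref_flat[active]) ** 2 / delta**2
            np.fmin(gamma2[active], cand, out=cand)
            gamma2[active] = cand
        # a voxel can only improve if the next shell's spatial term beats it
        next_spatial2 = (lengths[j] / dta) ** 2 if j < n_off else np.inf
        active = active[gamma2[active] > next_spatial2]
        i = j

    gamma = np.sqrt(gamma2)
    # tolerance keeps exact boundary cases (gamma == 1) from failing on
    # floating-point round-off
    pass_percent = 100.0 * float(np.count_nonzero(gamma <= 1.0 + 1e-9)) / n_eval
    gm = None
    if keep_map:
        full = np.zeros(geom.dims)
        full[evaluated] = gamma
        gm = ScalarVolume(geom, full, Quantity.DIMENSIONLESS)
    return GammaResult(criteria, gm, pass_percent, n_eval, evaluated, dnorm)


def gamma_sweep(
    ref: ScalarVolume,
    eval_: ScalarVolume,
    dose_percents: Sequence[float] = (1.0, 2.0, 3.0, 5.0),
    dta_mms: Sequence[float] = (1.0, 2.0, 3.0),
    threshold_percent: float = 10.0,
    refinement: int = 3,
    norm_dose: Optional[float] = None,
    region: Optional[np.ndarray] = None,
    keep_maps: bool = False,
) -> list[GammaResult]:
    """Gamma pass rates over the standard 12-criterion grid (4 dose
    tolerances x 3 DTA values, 10% threshold)."""
    results = []
    for dp in dose_percents:
        for dta in dta_mms:
            crit = GammaCriteria(dose_percent=dp, dta_mm=dta, threshold_percent=threshold_percent)
            results.append(
                gamma_3d(
                    ref,
                    eval_,
                    crit,
                    refinement=refinement,
                    norm_dose=norm_dose,
                    region=region,
                    keep_map=keep_maps,
                )
            )
    return results


def sweep_table(results: Sequence[GammaResult]) -> list[dict]:
    """Rows of (dose %, DTA mm, pass %, evaluated voxels) for reporting."""
    return [
        {
            "dose_percent": r.criteria.dose_percent,
            "dta_mm": r.criteria.dta_mm,
            "threshold_percent": r.criteria.threshold_percent,
            "pass_percent": r.pass_percent,
            "evaluated_voxels": r.evaluated_voxel_count,
        }
        for r in results
    ]
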