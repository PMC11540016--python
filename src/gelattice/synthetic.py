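"""Synthetic phantom, plan dose, and CBCT gel-scan generator.

Emulates the study conditions end-to-end so every pipeline stage is
testable without clinical data: a ~2 L cylindrical gel jar whose body
contour contracted by 2 cm gives the 575.7 cm^3 cylindrical surrogate GTV
(r = 45 mm, h = 90.5 mm), a multi-sphere LRT dose distribution with peaks
near 25 Gy and valleys around 30% of maximum, and six noisy pre- plus six
noisy post-irradiation CBCT scans whose dose response follows the tanh
calibration curve ``dN = alpha + beta * tanh(gamma * D - phi)``.

The generated truth bundle (noiseless response, true dose, true curve) is
the oracle for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import VolumeGeometry
from .readout import CalibrationCurve, tanh_response
from .volumes import Quantity, ScalarVolume, StructureMask
from .lattice import VertexSet

__all__ = [
    "PhantomSpec",
    "GelSimConfig",
    "SimTruth",
    "make_cylinder_mask",
    "make_plan_dose",
    "simulate_cbct_pair",
    "canonical_gtv_spec",
    "canonical_jar_spec",
    "default_sim_curve",
]

#: surrogate GTV: radius/height reproducing the printed 575.7 cm^3 exactly
GTV_RADIUS_MM = 45.0
GTV_HEIGHT_MM = 90.5
#: 2 L jar surrogate = GTV expanded 20 mm radially and axially (both ends)
JAR_RADIUS_MM = 65.0
JAR_HEIGHT_MM = 130.5


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical phantom centered in its voxel grid (lengths in mm)."""

    radius: float
    height: float
    grid: VolumeGeometry
    shape: str = "cylinder"

    def __post_init__(self) -> None:
        if self.shape != "cylinder":
            raise ValueError(f"unsupported phantom shape '{self.shape}'")
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("radius and height must be > 0")


def _grid_for_cylinder(radius: float, height: float, spacing: float) -> VolumeGeometry:
    n_xy = int(math.ceil(2 * radius / spacing)) + 5
    n_z = int(math.ceil(height / spacing)) + 5
    return VolumeGeometry.centered((n_xy, n_xy, n_z), (spacing, spacing, spacing))


def canonical_gtv_spec(spacing: float = 1.0) -> PhantomSpec:
    """The cylindrical surrogate GTV (575.7 cm^3) on an isotropic grid."""
    return PhantomSpec(GTV_RADIUS_MM, GTV_HEIGHT_MM, _grid_for_cylinder(GTV_RADIUS_MM, GTV_HEIGHT_MM, spacing))


def canonical_jar_spec(spacing: float = 1.0) -> PhantomSpec:
    """The gel-jar surrogate (~1.7 L fill of a nominal 2 L jar)."""
    return PhantomSpec(JAR_RADIUS_MM, JAR_HEIGHT_MM, _grid_for_cylinder(JAR_RADIUS_MM, JAR_HEIGHT_MM, spacing))


def make_cylinder_mask(spec: PhantomSpec, name: str = "cylinder") -> StructureMask:
    """Voxel centers with ``x^2 + y^2 <= r^2`` and ``|z| <= h/2``, cylinder
    centered at the world origin (grid must be centered / contain it)."""
    geom = spec.grid
    x, y, z = geom.coordinate_grids()
    # the cylinder must fit inside the grid's voxel-center extent
    for ax, need in ((0, spec.radius), (1, spec.radius), (2, spec.height / 2.0)):
        coords = geom.axis_coords(ax)
        if coords.min() > -need + 1e-9 or coords.max() < need - 1e-9:
            raise ValueError(
                f"cylinder (r={spec.radius}, h={spec.height}) exceeds grid extent on axis {ax}"
            )
    inside = (x**2 + y**2 <= spec.radius**2 + 1e-9) & (np.abs(z) <= spec.height / 2.0 + 1e-9)
    return StructureMask(geom, np.broadcast_to(inside, geom.dims).copy(), name=name)


@dataclass(frozen=True)
class GelSimConfig:
    """Gel/CBCT simulation conditions.

    ``noise_sd`` is the per-scan i.i.d. Gaussian noise in CBCT numbers
    (default 1% of the curve amplitude beta); ``ring_amplitude`` is the
    radial remnant pattern surviving background subtraction (added to the
    post-irradiation scans only), with period ``ring_period_mm``.
    """

    curve: CalibrationCurve = field(
        default_factory=lambda: CalibrationCurve(alpha=40.0, beta=60.0, gamma_=0.08, phi=0.3)
    )
    noise_sd: float = 0.6
    n_scans: int = 6
    ring_amplitude: float = 2.0
    ring_period_mm: float = 15.0
    base_value: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")


@dataclass
class SimTruth:
    """Ground truth stored alongside simulated scans (pipeline oracles)."""

    dose: ScalarVolume
    noiseless_delta: ScalarVolume
    curve: CalibrationCurve
    gel_mask: StructureMask


def make_plan_dose(
    vset: VertexSet,
    rx: float,
    peak: float,
    sphere_radius: float,
    penumbra_w: float,
    valley_floor_frac: float,
    grid: VolumeGeometry,
    rx_diameter_mm: float | None = None,
    valley_range_mm: float = 28.0,
    valley_falloff_mm: float = 3.0,
) -> ScalarVolume:
    """Analytic multi-sphere LRT dose distribution.

    ``D(p) = peak * [f * E(p) + (1 - f) * max_c sigma((r0 - |p - c|)/w)]``
    with ``sigma`` the logistic function, ``f`` the valley floor fraction
    and ``r0`` chosen in closed form so the dose equals ``rx`` at radius
    ``rx_diameter_mm / 2`` from each center (default: the nominal sphere
    radius). ``E(p) = sigma((valley_range_mm - d_min(p)) / valley_falloff_mm)``
    (``d_min`` = distance to the nearest vertex) carries the valley dose
    inside the lattice and lets the dose fall toward zero at the jar
    periphery, so a central slice spans the full 0-to-peak dose range.
    Deterministic given its inputs.
    """
    if peak < rx:
        raise ValueError("peak must be >= rx")
    if not (0 <= valley_floor_frac < 1):
        raise ValueError("valley_floor_frac must be in [0, 1)")
    if len(vset) == 0:
        raise ValueError("vertex set is empty")
    centers = vset.centers
    idx = grid.world_to_index(centers)
    if not np.all(grid.contains_index(idx)):
        raise ValueError("vertex centers outside the dose grid")
    r_rx = (2.0 * sphere_radius if rx_diameter_mm is None else rx_diameter_mm) / 2.0
    # solve sigma((r0 - r_rx)/w) = q  =>  r0 = r_rx + w * logit(q)
    q = (rx / peak - valley_floor_frac) / (1.0 - valley_floor_frac)
    if not (0 < q < 1):
        raise ValueError("rx/peak/valley_floor_frac leave no logistic solution")
    r0 = r_rx + penumbra_w * math.log(q / (1.0 - q))

    x, y, z = grid.coordinate_grids()
    peak_term = np.zeros(grid.dims)
    d_min = np.full(grid.dims, np.inf)
    for c in centers:
        r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        np.minimum(d_min, r, out=d_min)
        np.maximum(peak_term, 1.0 / (1.0 + np.exp((r - r0) / penumbra_w)), out=peak_term)
    envelope = 1.0 / (1.0 + np.exp((d_min - valley_range_mm) / valley_falloff_mm))
    dose = peak * (valley_floor_frac * envelope + (1.0 - valley_floor_frac) * peak_term)
    return ScalarVolume(grid, dose, Quantity.DOSE_GY)


def simulate_cbct_pair(
    dose: ScalarVolume,
    phantom: StructureMask,
    cfg: GelSimConfig,
) -> tuple[list[ScalarVolume], list[ScalarVolume], SimTruth]:
    """Six-plus-six (by default) noisy CBCT scan pairs for a gel phantom.

    Pre-irradiation scans are ``base + noise``; post-irradiation scans add
    the tanh dose response of the gel (inside the phantom) and the remnant
    ring pattern. Fully reproducible from ``cfg.seed``; scans draw
    sequentially from one generator (all pre scans, then all post scans).
    """
    dose.geometry.require_compatible(phantom.geometry, what="dose vs phantom")
    geom = dose.geometry
    inside = phantom.values
    base = np.where(inside, cfg.base_value, 0.0)
    response = np.where(inside, tanh_response(dose.values, cfg.curve), 0.0)
    if cfg.ring_amplitude != 0.0:
        x, y, _ = geom.coordinate_grids()
        r = np.broadcast_to(np.sqrt(x**2 + y**2), geom.dims)
        ring = np.where(
            inside, cfg.ring_amplitude * np.sin(2.0 * np.pi * r / cfg.ring_period_mm), 0.0
        )
    else:
        ring = 0.0
    rng = np.random.default_rng(cfg.seed)

    def _noisy(field: np.ndarray) -> ScalarVolume:
        noise = rng.normal(0.0, cfg.noise_sd, size=geom.dims) if cfg.noise_sd > 0 else 0.0
        return ScalarVolume(geom, field + noise, Quantity.CBCT_NUMBER)

    pre_scans = [_noisy(base) for _ in range(cfg.n_scans)]
    post_scans = [_noisy(base + response + ring) for _ in range(cfg.n_scans)]
    truth = SimTruth(
        dose=dose,
        noiseless_delta=ScalarVolume(geom, response, Quantity.DELTA_CBCT),
        curve=cfg.curve,
        gel_mask=phantom,
    )
    return pre_scans, post_scans, truth
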