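"""Shared fixtures: canonical synthetic phantom, lattice and a full
simulated readout bundle (generated once per session)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from scipy import ndimage

import gelattice as gl


@pytest.fixture(scope="session")
def gtv_mask():
    """Cylindrical surrogate GTV (r=45 mm, h=90.5 mm) on a 1 mm grid."""
    return gl.make_cylinder_mask(gl.canonical_gtv_spec(1.0), name="GTV")


@pytest.fixture(scope="session")
def lattice_19(gtv_mask):
    """The canonical 19-vertex HCP lattice (d=15 mm, s=30 mm, centroid anchor)."""
    return gl.build_lattice(gl.LatticeSpec(), gtv_mask, anchor="centroid")


@dataclass
class SimBundle:
    grid: gl.VolumeGeometry
    gtv: gl.StructureMask
    jar: gl.StructureMask
    vset: gl.VertexSet
    plan: gl.ScalarVolume
    pre: list
    post: list
    truth: gl.SimTruth
    gel_dose: gl.ScalarVolume
    curve: gl.CalibrationCurve
    info: dict

    def eval_mask(self, margin: int = 3) -> np.ndarray:
        """Gel region minus a wall margin (container-wall partial-volume
        voxels are excluded from voxelwise accuracy metrics)."""
        return ndimage.binary_erosion(self.jar.values, iterations=margin)


@pytest.fixture(scope="session")
def sim_bundle():
    """Full end-to-end synthetic study at 1 mm: 19-vertex plan on the jar
    phantom, 6+6 scans at 1% noise, readout chain to calibrated dose."""
    from gelattice.pipeline import readout_chain

    jar_spec = gl.canonical_jar_spec(1.0)
    grid = jar_spec.grid
    gtv = gl.make_cylinder_mask(gl.PhantomSpec(45.0, 90.5, grid), name="GTV")
    jar = gl.make_cylinder_mask(jar_spec, name="gel")
    vset = gl.build_lattice(gl.LatticeSpec(), gtv, anchor="centroid")
    plan = gl.make_plan_dose(
        vset, rx=20.0, peak=24.9, sphere_radius=7.5, penumbra_w=1.8,
        valley_floor_frac=0.3, grid=grid,
    )
    cfg = gl.GelSimConfig(seed=7)  # noise_sd = 1% of beta, 6+6 scans
    pre, post, truth = gl.simulate_cbct_pair(plan, jar, cfg)
    gel_dose, curve, info = readout_chain(pre, post, plan, jar)
    return SimBundle(grid, gtv, jar, vset, plan, pre, post, truth, gel_dose, curve, info)


def smooth_dose_field(seed, shape=(21, 21, 21), scale=4.0, lo=0.0, hi=20.0):
    """Seeded random smooth scalar field rescaled to [lo, hi]."""
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.normal(0, 1, shape), scale, mode="nearest")
    return lo + (hi - lo) * (f - f.min()) / (f.max() - f.min())
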