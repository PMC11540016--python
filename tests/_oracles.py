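"""Independent reference implementations used only to check the package.

These deliberately use the most transparent formulation available (plain
loops over an upsampled grid, all-pairs distances) rather than the
package's optimized code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def brute_force_gamma(ref, eval_, dose_percent, dta_mm, threshold_percent=10.0, refinement=8):
    """Exhaustive gamma: the evaluated dose is upsampled by ``refinement``
    via trilinear interpolation and every displacement on the fine grid
    within a data-derived radius bound is tried for every reference voxel.

    The bound ``R = dta * max_voxel(|dD(0)| / delta)`` is exact: no
    displacement beyond it can beat the zero-displacement candidate of any
    voxel. Returns (gamma values on evaluated voxels, evaluated mask).
    """
    geom = ref.geometry
    sp = np.asarray(geom.spacing)
    dnorm = ref.values.max()
    delta = dose_percent / 100.0 * dnorm
    evaluated = ref.values >= threshold_percent / 100.0 * dnorm
    n = np.asarray(geom.dims)
    fine_n = (n - 1) * refinement + 1
    ci = np.meshgrid(*[np.arange(fn) / refinement for fn in fine_n], indexing="ij")
    fine = ndimage.map_coordinates(
        eval_.values, np.array([g.ravel() for g in ci]), order=1
    ).reshape(fine_n)
    step = sp / refinement
    g2 = np.full(tuple(n), np.inf)
    g0 = np.abs(eval_.values - ref.values) / delta
    R = dta_mm * g0[evaluated].max() + float(np.linalg.norm(step))
    nmax = np.floor(R / step).astype(int)
    for ox in range(-nmax[0], nmax[0] + 1):
        dx2 = (ox * step[0]) ** 2
        for oy in range(-nmax[1], nmax[1] + 1):
            dxy2 = dx2 + (oy * step[1]) ** 2
            if dxy2 > R * R:
                continue
            for oz in range(-nmax[2], nmax[2] + 1):
                d2 = dxy2 + (oz * step[2]) ** 2
                if d2 > R * R:
                    continue
                window = []
                ok = True
                for a, o in zip(range(3), (ox, oy, oz)):
                    lo_i = max(0, int(np.ceil(-o / refinement)))
                    hi_i = min(n[a] - 1, (fine_n[a] - 1 - o) // refinement)
                    if hi_i < lo_i:
                        ok = False
                        break
                    window.append((lo_i, hi_i))
                if not ok:
                    continue
                src = tuple(
                    slice(lo_i * refinement + o, hi_i * refinement + o + 1, refinement)
                    for (lo_i, hi_i), o in zip(window, (ox, oy, oz))
                )
                dst = tuple(slice(lo_i, hi_i + 1) for lo_i, hi_i in window)
                cand = d2 / dta_mm**2 + (fine[src] - ref.values[dst]) ** 2 / delta**2
                np.minimum(g2[dst], cand, out=g2[dst])
    return np.sqrt(g2[evaluated]), evaluated


def all_pairs_min_distance(points: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance by direct enumeration."""
    points = np.asarray(points, dtype=float)
    best = np.inf
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            best = min(best, float(np.linalg.norm(points[i] - points[j])))
    return best
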