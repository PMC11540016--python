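"""Lattice-radiotherapy vertex placement.

Places high-dose sphere centers ("vertices") on a hexagonal close-packed
(HCP) or rectangular lattice and keeps only those whose sphere is fully
contained in a target structure, mirroring the semi-automated LRT planning
workflow: the user chooses sphere diameter, center-to-center spacing and an
optional in-plane (x, y) shift, and the tool fills the target.

HCP construction: "A" layers are triangular lattices with basis
``a1 = (s, 0, 0)`` and ``a2 = (s/2, s*sqrt(3)/2, 0)``; layer ``k`` sits at
``z = k * s * sqrt(2/3)`` and odd ("B") layers are offset in-plane by
``(s/2, s/(2*sqrt(3)))``. Every interior site of the infinite lattice has
exactly 12 nearest neighbours at distance ``s``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import VolumeGeometry
from .volumes import StructureMask

__all__ = [
    "LatticeSpec",
    "VertexSet",
    "generate_hcp_candidates",
    "generate_rect_candidates",
    "filter_contained",
    "filter_min_distance",
    "vertices_to_mask",
    "build_lattice",
]

_HCP_LAYER_FACTOR = math.sqrt(2.0 / 3.0)  # layer separation / spacing


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice pattern parameters (all lengths in mm).

    ``spacing`` is the center-to-center distance; spheres must not overlap,
    so ``spacing >= sphere_diameter`` is enforced at construction.
    """

    pattern: str = "hexagonal"
    sphere_diameter: float = 15.0
    spacing: float = 30.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown pattern '{self.pattern}'")
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be > 0")
        if self.spacing < self.sphere_diameter:
            raise ValueError(
                f"spacing ({self.spacing} mm) must be >= sphere diameter "
                f"({self.sphere_diameter} mm): vertices must not overlap"
            )

    @property
    def radius(self) -> float:
        return self.sphere_diameter / 2.0


@dataclass
class VertexSet:
    """Lattice sphere centers kept after containment filtering."""

    centers: np.ndarray  # (n, 3) world mm
    diameter: float
    anchor: np.ndarray | None = None  # lattice origin vertex, world mm

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)

    def __len__(self) -> int:
        return self.centers.shape[0]

    def min_pairwise_distance(self) -> float:
        if len(self) < 2:
            return math.inf
        d = self.centers[:, None, :] - self.centers[None, :, :]
        dist = np.sqrt((d**2).sum(axis=-1))
        return float(dist[np.triu_indices(len(self), k=1)].min())

    # ------------------------------------------------------------- export

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_mm", "y_mm", "z_mm", "label"])
            for i, c in enumerate(self.centers, start=1):
                writer.writerow([f"{c[0]:.6f}", f"{c[1]:.6f}", f"{c[2]:.6f}", i])

    def to_json(self, path: str, spec: LatticeSpec | None = None) -> None:
        payload = {
            "diameter_mm": self.diameter,
            "anchor_mm": None if self.anchor is None else list(self.anchor),
            "centers_mm": [list(c) for c in self.centers],
        }
        if spec is not None:
            payload["spec"] = {
                "pattern": spec.pattern,
                "sphere_diameter_mm": spec.sphere_diameter,
                "spacing_mm": spec.spacing,
                "shift_x_mm": spec.shift_x,
                "shift_y_mm": spec.shift_y,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "VertexSet":
        with open(path) as fh:
            payload = json.load(fh)
        anchor = payload.get("anchor_mm")
        return cls(
            centers=np.asarray(payload["centers_mm"], dtype=float).reshape(-1, 3),
            diameter=float(payload["diameter_mm"]),
            anchor=None if anchor is None else np.asarray(anchor, dtype=float),
        )


def _sorted_points(points: np.ndarray) -> np.ndarray:
    """Deterministic ordering: by z, then y, then x."""
    if points.size == 0:
        return points.reshape(0, 3)
    order = np.lexsort((points[:, 0], points[:, 1], points[:, 2]))
    return points[order]


def generate_hcp_candidates(
    spec: LatticeSpec,
    anchor: Sequence[float],
    bbox: tuple[Sequence[float], Sequence[float]],
) -> np.ndarray:
    """All HCP lattice sites inside an axis-aligned box.

    ``anchor`` is a lattice site on layer 0 (an A layer); ``bbox`` is
    ``(lower_corner, upper_corner)`` in world mm. The in-plane shift of the
    spec is added to every site. Returns an (n, 3) array sorted by
    (z, y, x); empty for a degenerate box.
    """
    if spec.pattern != "hexagonal":
        raise ValueError(f"generate_hcp_candidates requires hexagonal pattern, got '{spec.pattern}'")
    s = spec.spacing
    anchor = np.asarray(anchor, dtype=float)
    lo = np.asarray(bbox[0], dtype=float)
    hi = np.asarray(bbox[1], dtype=float)
    if np.any(hi <= lo):
        return np.zeros((0, 3))
    base = anchor + np.array([spec.shift_x, spec.shift_y, 0.0])
    dz = s * _HCP_LAYER_FACTOR
    a1 = np.array([s, 0.0])
    a2 = np.array([s / 2.0, s * math.sqrt(3.0) / 2.0])
    b_offset = np.array([s / 2.0, s / (2.0 * math.sqrt(3.0))])

    k_min = math.floor((lo[2] - base[2]) / dz) - 1
    k_max = math.ceil((hi[2] - base[2]) / dz) + 1
    # conservative in-plane index ranges from the bbox extent
    extent = float(np.linalg.norm(hi[:2] - lo[:2])) + 2 * s
    center_xy = (lo[:2] + hi[:2]) / 2.0
    n_j = math.ceil(extent / (s * math.sqrt(3.0) / 2.0)) + 2
    n_i = math.ceil(extent / s) + n_j  # a2 leans along x by s/2 per j step

    points = []
    for k in range(k_min, k_max + 1):
        layer_origin = base[:2] + (b_offset if k % 2 else 0.0)
        z = base[2] + k * dz
        if z < lo[2] - 1e-9 or z > hi[2] + 1e-9:
            continue
        # center the index search window on the bbox
        rel = center_xy - layer_origin
        j0 = round(rel[1] / a2[1])
        i0 = round((rel[0] - j0 * a2[0]) / a1[0])
        for j in range(j0 - n_j, j0 + n_j + 1):
            for i in range(i0 - n_i, i0 + n_i + 1):
                xy = layer_origin + i * a1 + j * a2
                if (
                    lo[0] - 1e-9 <= xy[0] <= hi[0] + 1e-9
                    and lo[1] - 1e-9 <= xy[1] <= hi[1] + 1e-9
                ):
                    points.append((xy[0], xy[1], z))
    return _sorted_points(np.asarray(points, dtype=float).reshape(-1, 3))


def generate_rect_candidates(
    spec: LatticeSpec,
    anchor: Sequence[float],
    bbox: tuple[Sequence[float], Sequence[float]],
) -> np.ndarray:
    """Cubic-grid lattice sites (period = spacing on all axes) inside a box."""
    if spec.pattern != "rectangular":
        raise ValueError(f"generate_rect_candidates requires rectangular pattern, got '{spec.pattern}'")
    s = spec.spacing
    anchor = np.asarray(anchor, dtype=float)
    lo = np.asarray(bbox[0], dtype=float)
    hi = np.asarray(bbox[1], dtype=float)
    if np.any(hi <= lo):
        return np.zeros((0, 3))
    base = anchor + np.array([spec.shift_x, spec.shift_y, 0.0])
    axes = []
    for ax in range(3):
        n_lo = math.ceil((lo[ax] - base[ax]) / s - 1e-9)
        n_hi = math.floor((hi[ax] - base[ax]) / s + 1e-9)
        axes.append(base[ax] + s * np.arange(n_lo, n_hi + 1))
    if any(a.size == 0 for a in axes):
        return np.zeros((0, 3))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return _sorted_points(grid)


def containment_depth(target: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from each inside-voxel center to the nearest
    outside-voxel center; 0 outside the mask."""
    return ndimage.distance_transform_edt(
        target.values, sampling=target.geometry.spacing
    )


def filter_contained(
    candidates: np.ndarray,
    target: StructureMask,
    radius: float,
    diameter: float | None = None,
    anchor: Sequence[float] | None = None,
) -> VertexSet:
    """Keep candidates whose sphere of ``radius`` lies entirely in the target.

    Containment is evaluated on the mask's Euclidean distance transform:
    a candidate is kept iff the transform at its containing voxel is
    >= ``radius``. An empty target yields an empty set (not an error).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 3)
    diameter = 2.0 * radius if diameter is None else float(diameter)
    if target.voxel_count == 0 or candidates.shape[0] == 0:
        return VertexSet(np.zeros((0, 3)), diameter, anchor)
    depth = containment_depth(target)
    idx = target.geometry.world_to_index(candidates)
    inside_grid = target.geometry.contains_index(idx)
    keep = np.zeros(candidates.shape[0], dtype=bool)
    valid = np.nonzero(inside_grid)[0]
    if valid.size:
        vi = idx[valid]
        keep[valid] = depth[vi[:, 0], vi[:, 1], vi[:, 2]] >= radius - 1e-9
    return VertexSet(_sorted_points(candidates[keep]), diameter, anchor)


def filter_min_distance(
    vset: VertexSet, other: StructureMask, min_distance: float
) -> VertexSet:
    """Drop vertices closer than ``min_distance`` (mm, center-to-surface) to a
    second structure — the manual organ-at-risk proximity filter."""
    if len(vset) == 0 or other.voxel_count == 0:
        return vset
    outside_dist = ndimage.distance_transform_edt(
        ~other.values, sampling=other.geometry.spacing
    )
    idx = other.geometry.world_to_index(vset.centers)
    inside_grid = other.geometry.contains_index(idx)
    keep = np.ones(len(vset), dtype=bool)
    for n, (ok, i) in enumerate(zip(inside_grid, idx)):
        if ok:
            keep[n] = outside_dist[i[0], i[1], i[2]] >= min_distance
    return VertexSet(vset.centers[keep], vset.diameter, vset.anchor)


def vertices_to_mask(
    vset: VertexSet, geometry: VolumeGeometry, labeled: bool = False
) -> StructureMask | np.ndarray:
    """Rasterize vertex spheres: voxels whose centers lie within
    ``diameter/2`` of any center. In labeled mode returns an int array with
    sphere ``i`` (1-based) written at its voxels; ties cannot occur while
    spacing >= diameter."""
    centers = vset.centers
    if centers.shape[0]:
        idx = geometry.world_to_index(centers)
        bad = ~geometry.contains_index(idx)
        if np.any(bad):
            raise ValueError(
                f"vertex centers outside grid extent: {centers[bad].tolist()}"
            )
    labels = np.zeros(geometry.dims, dtype=int)
    r = vset.diameter / 2.0
    x, y, z = geometry.coordinate_grids()
    spacing = np.asarray(geometry.spacing)
    for i, c in enumerate(centers, start=1):
        # local window around the sphere keeps this O(sphere volume)
        lo = np.maximum(geometry.world_to_index(c - r) - 1, 0)
        hi = np.minimum(geometry.world_to_index(c + r) + 2, geometry.dims)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        d2 = (
            (x[sl[0], :, :] - c[0]) ** 2
            + (y[:, sl[1], :] - c[1]) ** 2
            + (z[:, :, sl[2]] - c[2]) ** 2
        )
        labels[sl][d2 <= r * r] = i
    if labeled:
        return labels
    return StructureMask(geometry, labels > 0, name="lattice_vertices")


def build_lattice(
    spec: LatticeSpec,
    target: StructureMask,
    anchor: Sequence[float] | str = "centroid",
    bbox_margin: float = 0.0,
) -> VertexSet:
    """Generate candidates over the target bounding box, filter containment.

    ``anchor='centroid'`` anchors an A layer (with a vertex) at the target
    centroid — the convention that reproduces the published 19-sphere
    arrangement on the cylindrical surrogate GTV.
    """
    if isinstance(anchor, str):
        if anchor != "centroid":
            raise ValueError(f"unknown anchor rule '{anchor}'")
        anchor_pt = target.centroid_mm()
    else:
        anchor_pt = np.asarray(anchor, dtype=float)
    idx = np.argwhere(target.values)
    if idx.size == 0:
        return VertexSet(np.zeros((0, 3)), spec.sphere_diameter, anchor_pt)
    lo = target.geometry.index_to_world(idx.min(axis=0)) - bbox_margin
    hi = target.geometry.index_to_world(idx.max(axis=0)) + bbox_margin
    if spec.pattern == "hexagonal":
        cands = generate_hcp_candidates(spec, anchor_pt, (lo, hi))
    else:
        cands = generate_rect_candidates(spec, anchor_pt, (lo, hi))
    return filter_contained(
        cands, target, spec.radius, diameter=spec.sphere_diameter, anchor=anchor_pt
    )
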