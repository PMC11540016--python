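"""Voxel-grid geometry shared by all volumes.

World coordinates are right-handed and in millimetres: x left-right,
y anterior-posterior, z superior-inferior. ``origin`` is the world
position of the *center* of voxel (0, 0, 0); voxel indices are 0-based
and arrays are indexed ``values[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGeometry", "GeometryMismatchError"]

#: tolerance (mm) under which two geometries are considered identical
GEOMETRY_TOL_MM = 1e-6


class GeometryMismatchError(ValueError):
    """Raised when an operation receives volumes on incompatible grids."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Regular 3D voxel grid: origin (mm), per-axis spacing (mm), dims.

    A world point belongs to the voxel whose center is nearest, i.e. each
    voxel is the closed axis-aligned box of side ``spacing`` around its
    center.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must all be length-3")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n <= 0 for n in self.dims):
            raise ValueError(f"dims must be positive integers, got {self.dims}")

    # ---------------------------------------------------------------- helpers

    @classmethod
    def centered(
        cls, dims: tuple[int, int, int], spacing: tuple[float, float, float]
    ) -> "VolumeGeometry":
        """Grid whose world center coincides with the center of the voxel box."""
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(dims, spacing))
        return cls(origin=origin, spacing=spacing, dims=tuple(dims))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1), (1,ny,1), (1,1,nz) world-coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world_to_continuous_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points, shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices of world points (rounds half away from zero)."""
        ci = self.world_to_continuous_index(points)
        return np.asarray(np.floor(ci + 0.5), dtype=int)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains_index(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=-1)

    def compatible(self, other: "VolumeGeometry", tol: float = GEOMETRY_TOL_MM) -> bool:
        """True iff origin, spacing and dims agree within ``tol`` mm."""
        return (
            self.dims == other.dims
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
        )

    def require_compatible(self, other: "VolumeGeometry", what: str = "volumes") -> None:
        if not self.compatible(other):
            raise GeometryMismatchError(
                f"incompatible geometries for {what}: "
                f"{self.origin}/{self.spacing}/{self.dims} vs "
                f"{other.origin}/{other.spacing}/{other.dims}"
            )
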