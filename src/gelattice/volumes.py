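"""Scalar volumes, structure masks, and multi-scan arithmetic.

The CBCT gel-readout protocol acquires several pre- and post-irradiation
scans, averages each group voxelwise and subtracts the averaged background
from the averaged post-irradiation image to obtain the gel's dose response
``delta_cbct``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import GeometryMismatchError, VolumeGeometry

__all__ = [
    "Quantity",
    "ScalarVolume",
    "StructureMask",
    "average_volumes",
    "subtract_background",
]


class Quantity(str, Enum):
    """Physical quantity stored in a :class:`ScalarVolume`."""

    DOSE_GY = "dose_Gy"
    CBCT_NUMBER = "cbct_number"
    DELTA_CBCT = "delta_cbct"
    DIMENSIONLESS = "dimensionless"  # e.g. gamma maps


@dataclass
class ScalarVolume:
    """A 3D scalar field on a :class:`VolumeGeometry`.

    ``values`` is indexed ``[ix, iy, iz]`` (x fastest-varying world axis
    first). Dose volumes must be non-negative and all values finite.
    """

    geometry: VolumeGeometry
    values: np.ndarray
    quantity: Quantity

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.quantity = Quantity(self.quantity)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if self.values.shape != tuple(self.geometry.dims):
            raise ValueError(
                f"values shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.quantity is Quantity.DOSE_GY and np.any(self.values < 0):
            raise ValueError("dose_Gy volume contains negative values")

    def copy_with(self, values: np.ndarray, quantity: Quantity | None = None) -> "ScalarVolume":
        return ScalarVolume(
            geometry=self.geometry,
            values=np.asarray(values, dtype=float),
            quantity=self.quantity if quantity is None else quantity,
        )

    def crop(self, lo: Sequence[int], hi: Sequence[int]) -> "ScalarVolume":
        """Sub-volume by half-open voxel index ranges ``[lo, hi)`` per axis."""
        lo = [int(v) for v in lo]
        hi = [int(v) for v in hi]
        if any(l < 0 or h > n or h <= l for l, h, n in zip(lo, hi, self.geometry.dims)):
            raise ValueError(f"invalid crop ranges {lo}..{hi} for dims {self.geometry.dims}")
        geom = VolumeGeometry(
            origin=tuple(self.geometry.index_to_world(lo)),
            spacing=self.geometry.spacing,
            dims=tuple(h - l for l, h in zip(lo, hi)),
        )
        return ScalarVolume(geom, self.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy(), self.quantity)


@dataclass
class StructureMask:
    """Binary structure (target, phantom body, ...) on a voxel grid."""

    geometry: VolumeGeometry
    values: np.ndarray
    name: str = "structure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.values.ndim}")
        if self.values.shape != tuple(self.geometry.dims):
            raise ValueError(
                f"mask shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0

    def centroid_mm(self) -> np.ndarray:
        """World centroid of the set voxels (mask must be non-empty)."""
        if self.voxel_count == 0:
            raise ValueError(f"mask '{self.name}' is empty; centroid undefined")
        idx = np.argwhere(self.values)
        return self.geometry.index_to_world(idx.mean(axis=0))


def average_volumes(scans: Sequence[ScalarVolume]) -> ScalarVolume:
    """Voxelwise arithmetic mean of repeated scans on one grid.

    All scans must share a compatible geometry and the same quantity.
    """
    if len(scans) == 0:
        raise ValueError("average_volumes requires at least one scan")
    first = scans[0]
    for i, s in enumerate(scans[1:], start=1):
        first.geometry.require_compatible(s.geometry, what=f"scan 0 vs scan {i}")
        if s.quantity is not first.quantity:
            raise ValueError(
                f"mixed quantities: scan 0 is {first.quantity.value}, "
                f"scan {i} is {s.quantity.value}"
            )
    mean = np.mean([s.values for s in scans], axis=0)
    return ScalarVolume(first.geometry, mean, first.quantity)


def subtract_background(post_mean: ScalarVolume, pre_mean: ScalarVolume) -> ScalarVolume:
    """Background-subtracted image: averaged post minus averaged pre.

    Both inputs must be ``cbct_number`` volumes on compatible grids; the
    result carries quantity ``delta_cbct``.
    """
    post_mean.geometry.require_compatible(pre_mean.geometry, what="post vs pre")
    if post_mean.quantity is not Quantity.CBCT_NUMBER or pre_mean.quantity is not Quantity.CBCT_NUMBER:
        raise ValueError(
            "subtract_background expects cbct_number volumes, got "
            f"{post_mean.quantity.value} and {pre_mean.quantity.value}"
        )
    return ScalarVolume(
        post_mean.geometry, post_mean.values - pre_mean.values, Quantity.DELTA_CBCT
    )
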