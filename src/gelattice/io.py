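"""Volume and mask I/O.

NRRD is the canonical interchange format; NIfTI-1 is supported alongside.
DICOM RT Dose import is read-only (applies ``DoseGridScaling``, requires a
regular ``GridFrameOffsetVector``). Arrays are stored on disk in the usual
(z, y, x) order and transposed to this package's (x, y, z) convention.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import SimpleITK as sitk

from .geometry import VolumeGeometry
from .volumes import Quantity, ScalarVolume, StructureMask

__all__ = [
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dicom_rt_dose",
]

_QUANTITY_KEY = "gelattice_quantity"
_EXTENSIONS = {
    ".nrrd": "nrrd",
    ".nhdr": "nrrd",
    ".nii": "nifti",
    ".nii.gz": "nifti",
    ".dcm": "dicom_rt_dose",
}


class VolumeFormatError(ValueError):
    """Unreadable file or metadata violating the expected standard."""


def _format_from_path(path: str) -> str:
    lower = path.lower()
    for ext, fmt in _EXTENSIONS.items():
        if lower.endswith(ext):
            return fmt
    raise VolumeFormatError(f"cannot infer format from extension of '{path}'")


def _geometry_from_image(img: sitk.Image, path: str) -> VolumeGeometry:
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"'{path}': 3D volume required, file is {img.GetDimension()}D"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError(
            f"'{path}': only axis-aligned (identity direction) volumes are supported"
        )
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"'{path}': non-positive spacing metadata {spacing}")
    return VolumeGeometry(origin=tuple(img.GetOrigin()), spacing=tuple(spacing), dims=tuple(img.GetSize()))


def read_volume(
    path: str,
    format: Optional[str] = None,
    quantity: Optional[Quantity | str] = None,
) -> ScalarVolume:
    """Read a 3D scalar volume (NRRD, NIfTI, or DICOM RT Dose).

    The quantity is taken from file metadata when present (volumes written
    by :func:`write_volume` carry it); otherwise ``quantity`` must be given.
    DICOM RT Dose always yields ``dose_Gy``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _format_from_path(path)
    if fmt == "dicom_rt_dose":
        return read_dicom_rt_dose(path)
    if fmt not in ("nrrd", "nifti"):
        raise VolumeFormatError(f"unknown format '{fmt}'")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps all parse failures
        raise VolumeFormatError(f"'{path}': unreadable as {fmt}: {exc}") from exc
    geometry = _geometry_from_image(img, path)
    values = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
    if quantity is None:
        if img.HasMetaDataKey(_QUANTITY_KEY):
            quantity = img.GetMetaData(_QUANTITY_KEY)
        else:
            raise VolumeFormatError(
                f"'{path}': no stored quantity; pass quantity= explicitly"
            )
    return ScalarVolume(geometry, values, Quantity(quantity))


def write_volume(vol: ScalarVolume, path: str) -> None:
    """Write a volume as NRRD or NIfTI-1 (by extension), float64 values."""
    fmt = _format_from_path(path)
    if fmt == "dicom_rt_dose":
        raise VolumeFormatError("DICOM RT Dose export is not supported (read-only import)")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetOrigin(vol.geometry.origin)
    img.SetSpacing(vol.geometry.spacing)
    if fmt == "nrrd":  # NIfTI has no free-form key/value header
        img.SetMetaData(_QUANTITY_KEY, vol.quantity.value)
    sitk.WriteImage(img, path)


def read_mask(path: str, name: str = "structure") -> StructureMask:
    """Read a binary structure mask (non-zero voxels are inside)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise VolumeFormatError(f"'{path}': unreadable mask: {exc}") from exc
    geometry = _geometry_from_image(img, path)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0) != 0
    return StructureMask(geometry, values, name=name)


def write_mask(mask: StructureMask, path: str) -> None:
    """Write a mask as uint8 0/1 NRRD or NIfTI."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.values.transpose(2, 1, 0).astype(np.uint8))
    )
    img.SetOrigin(mask.geometry.origin)
    img.SetSpacing(mask.geometry.spacing)
    sitk.WriteImage(img, path)


def read_dicom_rt_dose(path: str) -> ScalarVolume:
    """Import a DICOM RT Dose grid as a ``dose_Gy`` volume.

    Applies ``DoseGridScaling`` and requires axis-aligned orientation and a
    uniformly spaced ``GridFrameOffsetVector``.
    """
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise VolumeFormatError(f"'{path}': unreadable DICOM: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise VolumeFormatError(f"'{path}': not an RT Dose object (Modality={getattr(ds, 'Modality', None)})")
    orientation = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    if not np.allclose(orientation, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise VolumeFormatError(f"'{path}': only axis-aligned RT Dose grids are supported")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if offsets.size < 2:
        raise VolumeFormatError(f"'{path}': RT Dose must have at least 2 frames")
    dz = np.diff(offsets)
    if not np.allclose(dz, dz[0], atol=1e-6):
        raise VolumeFormatError(f"'{path}': irregular GridFrameOffsetVector {offsets}")
    if dz[0] <= 0:
        raise VolumeFormatError(f"'{path}': GridFrameOffsetVector must increase")
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)  # (dy, dx)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    scaling = float(ds.DoseGridScaling)
    frames = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    if frames.ndim != 3:
        raise VolumeFormatError(f"'{path}': 3D dose grid required")
    values = frames.transpose(2, 1, 0)
    geometry = VolumeGeometry(
        origin=origin,
        spacing=(col_spacing, row_spacing, float(dz[0])),
        dims=values.shape,
    )
    return ScalarVolume(geometry, values, Quantity.DOSE_GY)
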