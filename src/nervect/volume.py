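"""Volumetric image containers and stack I/O.

All in-memory grey values live on a normalized [0,1] scale (the scale on
which staining contrast is reported); 16-bit integer files are mapped to
[0,1] at the I/O boundary by division by the dtype maximum. Arrays are
indexed ``(z, y, x)`` with XY the nerve cross-section and z the long axis
of the nerve. Physical positions are ``index * voxel_size_um`` at voxel
centres, 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import tifffile

__all__ = ["Volume", "Mask", "read_stack", "write_stack"]


@dataclass
class Volume:
    """A 3D greyscale volume with isotropic voxel size.

    Parameters
    ----------
    data
        Float array of shape ``(nz, ny, nx)`` with values in [0, 1].
    voxel_size_um
        Isotropic voxel edge length in micrometres (default 4).
    provenance
        Free-text processing history; appended to by pipeline stages.
    """

    data: np.ndarray
    voxel_size_um: float = 4.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x); got ndim={self.data.ndim}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"grey values must lie in [0, 1]; got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, note: str = "") -> "Volume":
        """Return a copy carrying new voxel data and an extended provenance."""
        prov = self.provenance if not note else (self.provenance + "; " + note).lstrip("; ")
        return Volume(data, voxel_size_um=self.voxel_size_um, provenance=prov)


@dataclass
class Mask:
    """A boolean volume aligned to a parent :class:`Volume`."""

    data: np.ndarray
    voxel_size_um: float = 4.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


_SUPPORTED_INT = {np.dtype(np.uint8): 255, np.dtype(np.uint16): 65535}


def read_stack(path: str | os.PathLike, voxel_size_um: float = 4.0) -> Volume:
    """Read a multi-page TIFF or NIfTI stack as a normalized Volume.

    Integer intensities are mapped to [0,1] by division by the dtype
    maximum; TIFF page order becomes z order. For NIfTI the voxel size is
    taken from the header spacing (mm, converted to μm) and overrides the
    ``voxel_size_um`` argument.
    """
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D NIfTI; got shape {arr.shape}")
        # file order (x, y, z) -> internal (z, y, x)
        arr = np.transpose(arr, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        voxel_size_um = float(zooms[0]) * 1000.0
        data = _normalize(arr)
        return Volume(data, voxel_size_um=voxel_size_um, provenance=f"read {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a single-channel multi-page TIFF; got shape {pages.shape}")
    data = _normalize(pages)
    return Volume(data, voxel_size_um=voxel_size_um, provenance=f"read {path}")


def _normalize(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return np.asarray(arr, dtype=np.float64)
    if arr.dtype not in _SUPPORTED_INT:
        raise ValueError(f"unsupported stack dtype {arr.dtype}; expected uint8, uint16 or float")
    return arr.astype(np.float64) / _SUPPORTED_INT[arr.dtype]


def write_stack(volume: Volume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a Volume as 16-bit multi-page TIFF or NIfTI-1.

    tiff16 stores ``round(grey * 65535)`` per voxel. NIfTI stores float32
    grey with the voxel size in the header spacing fields (μm as mm·1e-3)
    under an identity-orientation affine.
    """
    path = os.fspath(path)
    if format is None:
        format = "nifti" if path.endswith((".nii", ".nii.gz")) else "tiff16"
    if format == "tiff16":
        raw = np.round(volume.data * 65535.0).astype(np.uint16)
        tifffile.imwrite(path, raw, photometric="minisblack")
    elif format == "nifti":
        mm = volume.voxel_size_um * 1e-3
        affine = np.diag([mm, mm, mm, 1.0])
        arr = np.transpose(volume.data.astype(np.float32), (2, 1, 0))
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tiff16' or 'nifti'")
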