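"""Voxelized activity-concentration images.

A :class:`VoxelImage` is a reconstructed-like 3-D map of activity
concentration (kBq/ml) on a regular voxel grid.  All physical coordinates
are millimetres in a right-handed frame centred on the scanner field of
view; arrays are index-ordered ``(x, y, z)`` and ``origin`` is the physical
position of the centre of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage", "save_image", "load_image"]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 vector, got {x!r}")
    return v


@dataclass
class VoxelImage:
    """Activity-concentration volume on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Activity concentration in kBq/ml.
    voxel_size : float or (3,) array
        Voxel edge lengths in mm.
    origin : (3,) array
        Physical position (mm) of the centre of voxel ``(0, 0, 0)`` in the
        FOV-centred frame.
    meta : dict
        Free-form provenance (scanner name, seed, noiseless flag, ...).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.voxel_size = _as_vec3(self.voxel_size, "voxel_size")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mm^3 = 1e-3 ml)."""
        return float(np.prod(self.voxel_size)) * 1e-3

    @property
    def extent_mm(self) -> np.ndarray:
        """Cell-based physical edge lengths of the volume (mm)."""
        return np.asarray(self.shape) * self.voxel_size

    @property
    def center_mm(self) -> np.ndarray:
        """Physical centre of the voxel grid (mm)."""
        return self.origin + (np.asarray(self.shape) - 1) * self.voxel_size / 2.0

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (mm)."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin) / self.voxel_size

    def total_activity_kbq(self) -> float:
        """Spatial integral of the image: sum(value) * voxel volume [kBq]."""
        return float(self.values.sum() * self.voxel_volume_ml)


def _affine(img: VoxelImage) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = img.voxel_size
    aff[:3, 3] = img.origin
    return aff


def save_image(img: VoxelImage, path) -> None:
    """Write a VoxelImage as NIfTI-1 with mm spacing in the affine."""
    nifti = nib.Nifti1Image(img.values.astype(np.float32), _affine(img))
    nifti.header.set_xyzt_units("mm")
    if img.meta:
        nifti.header["descrip"] = json.dumps(img.meta)[:79].encode()
    nib.save(nifti, str(path))


def load_image(path) -> VoxelImage:
    """Read a NIfTI-1 volume; voxel spacing comes from the header."""
    nifti = nib.load(str(path))
    data = np.asarray(nifti.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = np.asarray(nifti.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(nifti.affine[:3, 3], dtype=float)
    return VoxelImage(values=data, voxel_size=zooms, origin=origin)
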