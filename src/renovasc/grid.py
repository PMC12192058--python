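"""Voxel grids with physical spacing.

Conventions used throughout the package:

* voxel arrays are indexed ``(i, j, k)`` along the world ``(x, y, z)`` axes,
  0-based, right-handed;
* world coordinates are in **mm**, voxel spacing metadata is stored in **µm**;
* ``world = origin_mm + index * spacing_um / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_nifti", "save_nifti"]


@dataclass
class VolumeGrid:
    """A 3D scalar or label voxel array with anisotropic spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Binary masks are boolean or {0, 1} integer arrays.
    spacing_um : array-like of 3 floats
        Voxel edge lengths along (x, y, z), micrometres.
    origin_mm : array-like of 3 floats
        World coordinate of the centre of voxel (0, 0, 0), millimetres.
    """

    data: np.ndarray
    spacing_um: np.ndarray = field(default_factory=lambda: np.array([100.0, 100.0, 100.0]))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_um = np.asarray(self.spacing_um, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid requires a 3D array, got ndim={self.data.ndim}")
        if self.spacing_um.shape != (3,) or np.any(self.spacing_um <= 0):
            raise ValueError("spacing_um must be 3 positive values")
        if self.origin_mm.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_mm(self) -> np.ndarray:
        return self.spacing_um / 1000.0

    def same_grid(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_um, other.spacing_um)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_mm + idx * self.spacing_mm

    def mask_world_coords(self) -> np.ndarray:
        """World coordinates (mm) of all nonzero voxels, shape (n, 3)."""
        return self.world_coords(np.argwhere(self.data))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points, shape (n, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin_mm) / self.spacing_mm

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different data."""
        return VolumeGrid(data, self.spacing_um.copy(), self.origin_mm.copy())


def save_nifti(grid: VolumeGrid, path: str) -> None:
    """Write a VolumeGrid as NIfTI; spacing goes in the header zooms (mm)."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag([*grid.spacing_mm, 1.0])
    affine[:3, 3] = grid.origin_mm
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(grid.spacing_mm))
    img.header["descrip"] = b"spacing stored in mm; source spacing given in um"
    nib.save(img, path)


def load_nifti(path: str) -> VolumeGrid:
    img = nib.load(path)
    affine = img.affine
    spacing_mm = np.array(img.header.get_zooms()[:3], dtype=float)
    origin_mm = affine[:3, 3].astype(float)
    return VolumeGrid(np.asarray(img.dataobj), spacing_mm * 1000.0, origin_mm)
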