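"""3-D scalar volumes with a voxel-to-mm affine.

``ScalarVolume`` is the common currency of the package: tract density
(streamline visitation) maps, DTI parameter maps (FA/MD/AD/RD), fMRI
Z-maps and binary ROI masks are all scalar grids living in one
registered space.  NIfTI I/O goes through nibabel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ScalarVolume", "center_ras_affine", "make_box_roi"]


def center_ras_affine(shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """RAS affine with isotropic voxels and the grid centered on the origin.

    With the grid centered, "left hemisphere" is unambiguously x < 0 mm,
    y increases anteriorly and z superiorly (radiological RAS convention).
    """
    shape = tuple(int(s) for s in shape)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_size_mm)
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return affine


@dataclass
class ScalarVolume:
    """A 3-D scalar grid plus its voxel-center -> mm affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ScalarVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) mm coordinates of voxel centers."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def grid_coords_mm(self) -> np.ndarray:
        """mm coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_mm(idx).reshape(self.shape + (3,))

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asanyarray(self.data), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine)


def make_box_roi(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    x_range_mm: tuple[float, float],
    y_range_mm: tuple[float, float],
    z_range_mm: tuple[float, float],
) -> ScalarVolume:
    """Binary mask of voxels whose mm center lies inside a closed box.

    Intervals are closed on both ends so the voxel membership is
    bit-exactly reproducible.  A box that misses the grid entirely
    yields an empty mask with a warning (not an error): seed boxes are
    routinely defined in a template frame larger than a cropped volume.
    """
    ranges = [tuple(map(float, r)) for r in (x_range_mm, y_range_mm, z_range_mm)]
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"box range must be ordered min <= max, got ({lo}, {hi})")
    vol = ScalarVolume(np.zeros(shape, dtype=np.uint8), affine)
    coords = vol.grid_coords_mm()
    inside = np.ones(shape, dtype=bool)
    for axis, (lo, hi) in enumerate(ranges):
        inside &= (coords[..., axis] >= lo) & (coords[..., axis] <= hi)
    if not inside.any():
        logger.warning("box ROI %s lies outside the grid; mask is empty", ranges)
    vol.data[inside] = 1
    return vol
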