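"""Voxel-grid data model and NIfTI I/O.

All volumes are 3D scalar images on an isotropic-or-not voxel grid with
axis order (x = left/right, y = anterior/posterior, z = superior/inferior),
i.e. LAS+ orientation. Files are reoriented to this convention at load time
so that all downstream geometry (sagittal-plane morphology, z-axis lesion
placement, axial-slice cropping) can use fixed axis indices: axis 0 is the
sagittal stacking direction, axis 2 the through-slice direction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "LabelMask", "read_volume", "write_volume"]

_AXCODES = ("L", "A", "S")


@dataclass(eq=False)
class VolumeGrid:
    """A 3D intensity image with voxel spacing in mm.

    Parameters
    ----------
    data
        3D array of finite scalar intensities (arbitrary MR units).
        Stored as float64 internally regardless of on-disk precision.
    spacing
        Voxel edge lengths in mm, one per axis; all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation_tag: str = "LAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.spacing, self.orientation_tag)

    def require_nonnegative(self) -> None:
        """Synthesis inputs must be non-negative (multiplicative contrast)."""
        if np.any(self.data < 0):
            raise ValueError("volume has negative intensities; multiplicative "
                             "contrast synthesis requires non-negative signal")


@dataclass(eq=False)
class LabelMask:
    """A binary 3D mask sharing the grid of the volumes it is combined with."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def copy(self) -> "LabelMask":
        return LabelMask(self.data.copy(), self.spacing)


def check_same_grid(a: VolumeGrid | LabelMask, b: VolumeGrid | LabelMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=1e-6):
        raise ValueError(f"grid spacing mismatch: {a.spacing} vs {b.spacing}")


def read_volume(path: str | os.PathLike, as_mask: bool = False) -> VolumeGrid | LabelMask:
    """Read a 3D NIfTI image, reorienting to LAS+.

    Parameters
    ----------
    path
        Path to a ``.nii`` or ``.nii.gz`` file containing a 3D image.
    as_mask
        If true, binarise at > 0.5 and return a :class:`LabelMask`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    ornt = nib.orientations.io_orientation(img.affine)
    target = nib.orientations.axcodes2ornt(_AXCODES)
    transform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(data, transform)
    zooms = img.header.get_zooms()[:3]
    spacing = [0.0, 0.0, 0.0]
    for src_axis in range(3):
        spacing[int(transform[src_axis, 0])] = float(zooms[src_axis])
    if as_mask:
        return LabelMask(data, tuple(spacing))
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return VolumeGrid(data, tuple(spacing))


def write_volume(grid: VolumeGrid | LabelMask, path: str | os.PathLike) -> None:
    """Write to NIfTI-1: masks as uint8, intensities as float32, LAS+ affine."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    sx, sy, sz = grid.spacing
    # +x points Left in LAS+, so the RAS affine negates the first axis.
    affine = np.diag([-sx, sy, sz, 1.0])
    if isinstance(grid, LabelMask):
        arr = grid.data.astype(np.uint8)
    else:
        arr = grid.data.astype(np.float32)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))
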