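"""Structuring elements and sagittal-plane morphology.

A "disc" is the set of integer in-plane offsets with Euclidean distance
<= r; a "ball" is its 3D analogue. Sagittal-plane operations act within
planes of constant x (axis 0), i.e. on the (y, z) axes, matching data in
LAS+ axis order where the in-plane spacing of a sagittal slice is small
and the between-slice spacing large.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "disc",
    "ball",
    "sagittal_structure",
    "dilate_sagittal",
    "erode_sagittal",
]


def disc(radius: int) -> np.ndarray:
    """2D disc: offsets (a, b) with a² + b² <= r²."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    a, b = np.meshgrid(ax, ax, indexing="ij")
    return (a * a + b * b) <= r * r


def ball(radius: int) -> np.ndarray:
    """3D ball: offsets with squared Euclidean norm <= r²."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    a, b, c = np.meshgrid(ax, ax, ax, indexing="ij")
    return (a * a + b * b + c * c) <= r * r


def sagittal_structure(radius: int) -> np.ndarray:
    """Disc embedded in 3D with extent 1 along x: per-sagittal-slice element."""
    return disc(radius)[np.newaxis, :, :]


def dilate_sagittal(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=sagittal_structure(radius))


def erode_sagittal(mask: np.ndarray, radius: int) -> np.ndarray:
    # border_value=0: voxels at the volume edge erode away, which keeps
    # eroded cord masks strictly interior.
    return ndi.binary_erosion(mask, structure=sagittal_structure(radius),
                              border_value=0)
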