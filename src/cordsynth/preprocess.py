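"""Isotropic resampling and straightened-cord representation.

The synthesis and evaluation pipeline operates on a "straightened" cord:
each axial slice is cropped to a fixed in-plane window centred on the
spinal-cord centroid of that slice and the windows are stacked along z.
Resampling uses trilinear interpolation for intensities and nearest
neighbour for masks, with voxel centres at (index + 0.5) * spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grid import LabelMask, VolumeGrid, check_same_grid

__all__ = [
    "resample_isotropic",
    "straighten",
    "straighten_companion",
    "Straightened",
    "WindowOffsets",
]


def resample_isotropic(grid: VolumeGrid | LabelMask,
                       target_spacing_mm: float) -> VolumeGrid | LabelMask:
    """Resample to isotropic spacing ``(t, t, t)``.

    Output shape is ``ceil(extent_mm / t)`` per axis. Intensity grids are
    interpolated trilinearly, masks with nearest neighbour. A grid already
    at the target spacing is returned value-identical.
    """
    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError("target spacing must be positive")
    if any(n < 2 for n in grid.shape):
        raise ValueError(f"degenerate axis in shape {grid.shape}")
    spacing = grid.spacing
    new_shape = tuple(int(math.ceil(n * s / t)) for n, s in zip(grid.shape, spacing))
    # voxel-centre alignment: new centre (i+0.5)*t lands at old index x/s-0.5
    axes = [((np.arange(n_new) + 0.5) * t / s) - 0.5
            for n_new, s in zip(new_shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    is_mask = isinstance(grid, LabelMask)
    src = grid.data.astype(np.float64)
    order = 0 if is_mask else 1
    out = ndi.map_coordinates(src, coords, order=order, mode="nearest")
    if is_mask:
        return LabelMask(out > 0.5, (t, t, t))
    return VolumeGrid(out, (t, t, t))


@dataclass
class WindowOffsets:
    """Per-slice window centres produced by :func:`straighten`.

    ``z_start``/``z_stop`` delimit the axial slices kept (first to last
    cord-containing slice, inclusive/exclusive); ``centres`` holds one
    integer (cx, cy) per kept slice; ``window`` is the in-plane size.
    """

    z_start: int
    z_stop: int
    centres: np.ndarray  # (n_slices, 2) int
    window: int
    source_shape: tuple[int, int, int]


@dataclass
class Straightened:
    volume: VolumeGrid
    cord_mask: LabelMask
    offsets: WindowOffsets

    def __iter__(self):
        return iter((self.volume, self.cord_mask))


def _crop_window(plane: np.ndarray, cx: int, cy: int, w: int) -> np.ndarray:
    """Extract a w×w window centred at (cx, cy), zero-padded at borders."""
    out = np.zeros((w, w), dtype=plane.dtype)
    half = w // 2
    x0, y0 = cx - half, cy - half
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + w, plane.shape[0]), min(y0 + w, plane.shape[1])
    if sx0 < sx1 and sy0 < sy1:
        out[sx0 - x0:sx1 - x0, sy0 - y0:sy1 - y0] = plane[sx0:sx1, sy0:sy1]
    return out


def _window_centres(cord: np.ndarray) -> tuple[int, int, np.ndarray]:
    """Rounded per-slice cord centroids, linearly interpolated across gaps."""
    has_cord = cord.any(axis=(0, 1))
    zs = np.flatnonzero(has_cord)
    if zs.size == 0:
        raise ValueError("cord mask is empty")
    z_start, z_stop = int(zs[0]), int(zs[-1]) + 1
    cx = np.empty(zs.size)
    cy = np.empty(zs.size)
    for n, z in enumerate(zs):
        ii, jj = np.nonzero(cord[:, :, z])
        cx[n], cy[n] = ii.mean(), jj.mean()
    z_all = np.arange(z_start, z_stop)
    centres = np.stack([
        np.rint(np.interp(z_all, zs, cx)).astype(int),
        np.rint(np.interp(z_all, zs, cy)).astype(int),
    ], axis=1)
    return z_start, z_stop, centres


def straighten(volume: VolumeGrid, cord_mask: LabelMask,
               window: int = 48) -> Straightened:
    """Crop each axial slice to a ``window``² patch centred on the cord.

    The window centre of a slice is the integer-rounded centroid of the
    cord mask in that slice; slices without cord between two cord-bearing
    slices get a centre linearly interpolated from their neighbours.
    Slices before the first / after the last cord-containing slice are
    dropped. Returns the straightened volume, the straightened cord mask
    and the per-slice offsets needed to transform companion masks.
    """
    check_same_grid(volume, cord_mask)
    z_start, z_stop, centres = _window_centres(cord_mask.data)
    n = z_stop - z_start
    vol_out = np.zeros((window, window, n))
    cord_out = np.zeros((window, window, n), dtype=bool)
    for i, z in enumerate(range(z_start, z_stop)):
        cx, cy = centres[i]
        vol_out[:, :, i] = _crop_window(volume.data[:, :, z], cx, cy, window)
        cord_out[:, :, i] = _crop_window(cord_mask.data[:, :, z], cx, cy, window)
    offsets = WindowOffsets(z_start, z_stop, centres, window, volume.shape)
    return Straightened(VolumeGrid(vol_out, volume.spacing),
                        LabelMask(cord_out, volume.spacing), offsets)


def straighten_companion(mask: LabelMask, offsets: WindowOffsets) -> LabelMask:
    """Apply the per-slice crop of a previous :func:`straighten` to a mask."""
    if mask.shape != offsets.source_shape:
        raise ValueError(f"mask shape {mask.shape} does not match straightened "
                         f"source {offsets.source_shape}")
    w = offsets.window
    n = offsets.z_stop - offsets.z_start
    out = np.zeros((w, w, n), dtype=bool)
    for i, z in enumerate(range(offsets.z_start, offsets.z_stop)):
        cx, cy = offsets.centres[i]
        out[:, :, i] = _crop_window(mask.data[:, :, z], cx, cy, w)
    return LabelMask(out, mask.spacing)
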