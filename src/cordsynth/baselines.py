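"""Comparison synthesis transforms: carving insertion and target-load
patch insertion.

Both baselines insert real lesions from source volumes into lesion-free
target volumes under the same straightened-grid framework as the
parametric synthesiser, working on standardised (zero-mean, unit-SD)
intensities so that absolute scale differences between acquisitions do
not dominate the pasted region.

Carving insertion copies the source region around a lesion whose extent
is a level set of the signed Euclidean distance to the lesion boundary
(negative inside), with the level lambda sampled per call, so the carved
region can be smaller or larger than the lesion mask. Target-load
insertion extracts per-lesion patches (full in-plane window, z-extent of
the lesion), augments them, and pastes them at random z positions until
a sampled total lesion load is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grid import LabelMask, VolumeGrid, check_same_grid
from .morphology import erode_sagittal

__all__ = [
    "standardise",
    "signed_distance",
    "carve_region",
    "carvemix_insert",
    "PatchLibrary",
    "extract_lesion_patches",
    "lesionmix_pop_insert",
    "LesionMixResult",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def standardise(volume: VolumeGrid) -> VolumeGrid:
    """Shift/scale to mean 0, SD 1 over all voxels."""
    sd = float(volume.data.std(ddof=0))
    if sd == 0:
        raise ValueError("cannot standardise a constant image")
    return VolumeGrid((volume.data - volume.data.mean()) / sd, volume.spacing)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance (voxels) to the mask boundary; strictly
    negative inside the mask, positive outside."""
    inside = ndi.distance_transform_edt(mask)
    outside = ndi.distance_transform_edt(~mask)
    return outside - inside


def carve_region(lesions: np.ndarray, lam: float) -> np.ndarray:
    """Level set {d <= lambda}; equals the lesion mask exactly at lambda=0
    and is nested in lambda."""
    return signed_distance(lesions) <= lam


def _sample_lambda(d: np.ndarray, rng: np.random.Generator,
                   grow_max_vox: float = 2.0) -> float:
    """Equal-probability mixture of shrink U(d_min/2, 0) and grow
    U(0, grow_max); d_min is the minimum signed distance inside."""
    d_min = float(d.min())
    if rng.uniform() < 0.5:
        return float(rng.uniform(d_min / 2.0, 0.0))
    return float(rng.uniform(0.0, grow_max_vox))


def carvemix_insert(target: VolumeGrid, source: VolumeGrid,
                    source_lesions: LabelMask, rng: np.random.Generator,
                    lam: float | None = None,
                    grow_max_vox: float = 2.0) -> tuple[VolumeGrid, LabelMask]:
    """Carve the source lesion region into the target at its original
    position.

    Both images are standardised first. The carved region is
    R = {v : d(v) <= lambda} with d the signed distance to the lesion
    boundary; target voxels in R are replaced by source voxels and the
    label is the lesion mask restricted to R. A source that is locally
    darker than the target produces a hypointense insertion — a known
    failure mode of carving insertion that standardisation reduces but
    does not remove.
    """
    check_same_grid(target, source)
    check_same_grid(target, source_lesions)
    if source_lesions.is_empty():
        raise ValueError("source lesion mask is empty")
    tgt = standardise(target)
    src = standardise(source)
    d = signed_distance(source_lesions.data)
    if lam is None:
        lam = _sample_lambda(d, rng, grow_max_vox)
    region = d <= lam
    out = tgt.data.copy()
    out[region] = src.data[region]
    label = source_lesions.data & region
    return VolumeGrid(out, target.spacing), LabelMask(label, target.spacing)


@dataclass
class LesionPatch:
    intensity: np.ndarray  # (W, W, b) standardised intensities
    mask: np.ndarray       # (W, W, b) bool
    load_mm3: float
    source_id: str = ""


@dataclass
class PatchLibrary:
    patches: list[LesionPatch]
    spacing: tuple[float, float, float]

    def loads(self) -> np.ndarray:
        return np.array([p.load_mm3 for p in self.patches])

    def load_percentiles(self, lo: float = 5, hi: float = 95) -> tuple[float, float]:
        loads = self.loads()
        return float(np.percentile(loads, lo)), float(np.percentile(loads, hi))


def extract_lesion_patches(volumes, lesion_masks, source_ids=None) -> PatchLibrary:
    """One (intensity, mask) patch per 26-connected lesion, cut from the
    standardised volume: full in-plane window, z-size = lesion z-extent."""
    volumes, lesion_masks = list(volumes), list(lesion_masks)
    if source_ids is None:
        source_ids = [f"vol_{i:04d}" for i in range(len(volumes))]
    patches = []
    spacing = volumes[0].spacing
    for vol, les, sid in zip(volumes, lesion_masks, source_ids):
        check_same_grid(vol, les)
        if les.is_empty():
            raise ValueError(f"{sid}: lesion mask is empty")
        std = standardise(vol)
        labels, n = ndi.label(les.data, structure=_STRUCT_26)
        for comp in range(1, n + 1):
            m = labels == comp
            zs = np.flatnonzero(m.any(axis=(0, 1)))
            z0, z1 = int(zs[0]), int(zs[-1]) + 1
            patches.append(LesionPatch(
                intensity=std.data[:, :, z0:z1].copy(),
                mask=m[:, :, z0:z1].copy(),
                load_mm3=float(m.sum()) * les.voxel_volume_mm3,
                source_id=f"{sid}/les{comp}"))
    return PatchLibrary(patches, spacing)


def _zoom_patch(intensity: np.ndarray, mask: np.ndarray,
                factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic rescale, then centre crop/pad back to the original shape."""
    zi = ndi.zoom(intensity, factor, order=1)
    zm = ndi.zoom(mask.astype(np.float64), factor, order=0) > 0.5
    out_i = np.zeros_like(intensity)
    out_m = np.zeros_like(mask)
    for arr_src, arr_dst in ((zi, out_i), (zm, out_m)):
        src_sl, dst_sl = [], []
        for d in range(3):
            ns, nd = arr_src.shape[d], arr_dst.shape[d]
            if ns >= nd:
                off = (ns - nd) // 2
                src_sl.append(slice(off, off + nd))
                dst_sl.append(slice(0, nd))
            else:
                off = (nd - ns) // 2
                src_sl.append(slice(0, ns))
                dst_sl.append(slice(off, off + ns))
        arr_dst[tuple(dst_sl)] = arr_src[tuple(src_sl)]
    return out_i, out_m


def _elastic_deform(intensity: np.ndarray, mask: np.ndarray,
                    rng: np.random.Generator, max_disp_vox: float = 4.0,
                    grid_points: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth deformation from a coarse displacement grid."""
    shape = intensity.shape
    disp = [rng.uniform(-max_disp_vox, max_disp_vox,
                        size=(grid_points,) * 3) for _ in range(3)]
    fields = [ndi.zoom(d, [s / grid_points for s in shape], order=1,
                       mode="nearest") for d in disp]
    fields = [np.resize(f, shape) if f.shape != shape else f for f in fields]
    base = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = [b + f for b, f in zip(base, fields)]
    out_i = ndi.map_coordinates(intensity, coords, order=1, mode="nearest")
    out_m = ndi.map_coordinates(mask.astype(np.float64), coords, order=0,
                                mode="constant") > 0.5
    return out_i, out_m


def _rotate_patch(intensity: np.ndarray, mask: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rotation about z up to +/-89 deg, about x/y within +/-5 deg."""
    from .shapes import _rotation_matrix
    angles = (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(-89, 89))
    rot = _rotation_matrix(angles)
    centre = (np.asarray(intensity.shape, dtype=np.float64) - 1) / 2
    axes = [np.arange(s) for s in intensity.shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).astype(np.float64)
    src = (grid - centre) @ rot + centre  # rot.T.T: inverse map uses R^T = R^-1
    coords = [src[..., d] for d in range(3)]
    out_i = ndi.map_coordinates(intensity, coords, order=1, mode="nearest")
    out_m = ndi.map_coordinates(mask.astype(np.float64), coords, order=0,
                                mode="constant") > 0.5
    return out_i, out_m


def _augment_patch(patch: LesionPatch, rng: np.random.Generator,
                   noise_sd: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Flips, scaling, rotation, elastic deformation, gamma, noise."""
    intensity, mask = patch.intensity.copy(), patch.mask.copy()
    for axis in range(3):
        if rng.uniform() < 0.5:
            intensity = np.flip(intensity, axis=axis)
            mask = np.flip(mask, axis=axis)
    if rng.uniform() < 0.5:
        intensity, mask = _zoom_patch(intensity, mask, float(rng.uniform(0.5, 1.8)))
    if rng.uniform() < 0.5:
        intensity, mask = _rotate_patch(intensity, mask, rng)
    if rng.uniform() < 0.5 and mask.any():
        intensity, mask = _elastic_deform(intensity, mask, rng)
    # gamma transform on a non-negative shifted range, then shift back
    gamma = float(np.exp(rng.uniform(-0.3, 0.3)))
    lo_v, hi_v = float(intensity.min()), float(intensity.max())
    if hi_v > lo_v:
        unit = (intensity - lo_v) / (hi_v - lo_v)
        intensity = unit ** gamma * (hi_v - lo_v) + lo_v
    intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return intensity, mask


@dataclass
class LesionMixResult:
    volume: VolumeGrid
    label: LabelMask
    target_load_mm3: float
    achieved_load_mm3: float
    draws_used: int

    def __iter__(self):
        return iter((self.volume, self.label))


def lesionmix_pop_insert(target: VolumeGrid, cord: LabelMask,
                         library: PatchLibrary,
                         rng: np.random.Generator,
                         load_percentiles: tuple[float, float] | None = None,
                         max_draws: int = 50,
                         noise_sd: float = 0.1) -> LesionMixResult:
    """Insert augmented lesion patches until a sampled target load is met.

    The target load is drawn uniformly between the 5th and 95th
    percentiles of the library's per-lesion loads (or the given bounds).
    Each draw augments a random patch, places it at a random z position,
    removes voxels outside the sagittally-eroded cord, and pastes the
    patch intensities at the surviving mask voxels of the standardised
    target. Insertion stops when the achieved load reaches the target or
    the draw budget is exhausted.
    """
    check_same_grid(target, cord)
    if not library.patches:
        raise ValueError("patch library is empty")
    if load_percentiles is None:
        load_percentiles = library.load_percentiles()
    p_lo, p_hi = load_percentiles
    target_load = float(rng.uniform(p_lo, p_hi))
    std = standardise(target)
    out = std.data.copy()
    gt = np.zeros(target.shape, dtype=bool)
    eroded = erode_sagittal(cord.data, 1)
    voxvol = target.voxel_volume_mm3
    achieved = 0.0
    draws = 0
    zdim = target.shape[2]
    while achieved < target_load and draws < max_draws:
        draws += 1
        patch = library.patches[int(rng.integers(len(library.patches)))]
        intensity, mask = _augment_patch(patch, rng, noise_sd)
        b = mask.shape[2]
        if b > zdim or not mask.any():
            continue
        z0 = int(rng.integers(0, zdim - b + 1))
        w0 = min(mask.shape[0], target.shape[0])
        w1 = min(mask.shape[1], target.shape[1])
        sl = (slice(0, w0), slice(0, w1), slice(z0, z0 + b))
        placed = np.zeros(target.shape, dtype=bool)
        placed[sl] = mask[:w0, :w1, :]
        placed &= eroded
        placed &= ~gt  # no overlap with previously inserted lesions
        if not placed.any():
            continue
        full_int = np.zeros(target.shape)
        full_int[sl] = intensity[:w0, :w1, :]
        out[placed] = full_int[placed]
        gt |= placed
        achieved += float(placed.sum()) * voxvol
    return LesionMixResult(VolumeGrid(out, target.spacing),
                           LabelMask(gt, target.spacing),
                           target_load, achieved, draws)
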