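"""Synthetic lesion intensity profiles and full-volume synthesis.

Three composable steps give a lesion its appearance inside a candidate
mask M_c:

1. flat multiplicative increase: I* = (1 + c) I, so the mean intensity
   in the mask rises by exactly the sampled contrast factor c;
2. size-adaptive Gaussian gradient: I* = I (1 + A exp(-sum_m
   (m - m0)^2 / (2 sigma_m^2))) with sigma_m ~ U(l_m/8, l_m) per axis and
   amplitude A = c |M_c| / sum_{v in M_c} exp(...), which makes the
   mask-mean of the relative increase equal c; a floor keeps the relative
   increase at >= 0.015 everywhere in the mask so no part of the lesion
   is left without signal;
3. local homogenising Gaussian blur (sigma 0.67 voxels, kernel truncated
   at 2 voxels) written back only at mask voxels, lowering within-lesion
   variance while leaving every outside voxel bit-identical.

``synthesize_volume`` composes shape selection, augmentation, placement,
contrast sampling and the steps above into the end-to-end generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .contrast import ContrastParams, sample_contrast
from .grid import LabelMask, VolumeGrid, check_same_grid
from .shapes import ShapeLibrary, augment_shape, mask_geometry, place_shape, select_shape
from .morphology import erode_sagittal

__all__ = [
    "GaussianProfile",
    "SynthesisConfig",
    "flat_increase",
    "fit_gaussian_profile",
    "apply_profile",
    "local_blur",
    "synthesize_volume",
]


@dataclass
class GaussianProfile:
    """Anisotropic Gaussian hyperintensity profile over a candidate mask."""

    sigmas: tuple[float, float, float]  # voxels, one per axis
    amplitude: float
    centre: tuple[float, float, float]  # voxel coordinates (centre of mass)

    def relative_increase(self, coords: np.ndarray) -> np.ndarray:
        """A * exp(-sum (coord - centre)^2 / (2 sigma^2)) at voxel coords."""
        d = (coords.astype(np.float64) - np.asarray(self.centre)) ** 2
        expo = (d / (2.0 * np.asarray(self.sigmas, dtype=np.float64) ** 2)).sum(axis=1)
        return self.amplitude * np.exp(-expo)


@dataclass
class SynthesisConfig:
    """Tunable parameters of the synthesis pipeline (defaults as studied)."""

    use_gradient: bool = True
    use_blur: bool = True
    min_increase: float = 0.015
    blur_truncation_radius_vox: int = 2
    blur_sigma_vox: float = 0.67
    max_lesions_per_volume: int = 8
    neighbourhood_dilation_radius_vox: int = 5
    cord_erosion_radius_vox: int = 1
    p_affine_augment: float = 0.5
    p_erode: float = 0.25
    p_dilate: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_increase < 0:
            raise ValueError("min_increase must be >= 0")
        if self.blur_sigma_vox <= 0 or self.blur_truncation_radius_vox <= 0:
            raise ValueError("blur parameters must be positive")
        if self.max_lesions_per_volume < 0:
            raise ValueError("max_lesions_per_volume must be >= 0")


def flat_increase(volume: VolumeGrid, mask: LabelMask, c: float) -> VolumeGrid:
    """I* = (1 + c) I inside the mask, unchanged outside."""
    check_same_grid(volume, mask)
    if mask.is_empty():
        raise ValueError("mask is empty")
    if c <= -1:
        raise ValueError("contrast factor must exceed -1")
    out = volume.data.copy()
    out[mask.data] *= (1.0 + c)
    return VolumeGrid(out, volume.spacing)


def fit_gaussian_profile(mask: LabelMask, c: float,
                         rng: np.random.Generator,
                         sigmas: tuple[float, float, float] | None = None
                         ) -> GaussianProfile:
    """Draw per-axis decay scales sigma_m ~ U(l_m/8, l_m) and normalise the
    amplitude so the mask-mean relative increase equals c.

    ``sigmas`` overrides the random draw (for tests and ablations).
    """
    if mask.is_empty():
        raise ValueError("mask is empty")
    if c <= 0:
        raise ValueError("contrast factor must be positive for a profile")
    _, centroid, lengths = mask_geometry(mask)
    if sigmas is None:
        sigmas = tuple(float(rng.uniform(l / 8.0, float(l))) for l in lengths)
    coords = np.argwhere(mask.data)
    prof = GaussianProfile(sigmas=tuple(sigmas), amplitude=1.0, centre=centroid)
    expsum = prof.relative_increase(coords).sum()
    prof.amplitude = c * len(coords) / expsum
    return prof


def apply_profile(volume: VolumeGrid, mask: LabelMask, profile: GaussianProfile,
                  min_increase: float = 0.015) -> VolumeGrid:
    """Multiply mask voxels by 1 + max(A exp(...), min_increase)."""
    check_same_grid(volume, mask)
    if mask.is_empty():
        raise ValueError("mask is empty")
    coords = np.argwhere(mask.data)
    rel = np.maximum(profile.relative_increase(coords), min_increase)
    out = volume.data.copy()
    out[coords[:, 0], coords[:, 1], coords[:, 2]] *= (1.0 + rel)
    return VolumeGrid(out, volume.spacing)


def local_blur(volume: VolumeGrid, mask: LabelMask,
               truncation_radius_vox: int = 2,
               sigma_vox: float = 0.67) -> VolumeGrid:
    """Gaussian blur computed over the mask's padded bounding box, written
    back only at mask voxels; all outside voxels stay bit-identical."""
    check_same_grid(volume, mask)
    if mask.is_empty():
        raise ValueError("mask is empty")
    r = int(truncation_radius_vox)
    coords = np.argwhere(mask.data)
    lo = np.maximum(coords.min(axis=0) - r, 0)
    hi = np.minimum(coords.max(axis=0) + r + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = volume.data[sl]
    # truncate is chosen so the kernel half-width int(truncate*sigma + 0.5)
    # equals the requested radius in voxels
    blurred = ndi.gaussian_filter(sub, sigma=sigma_vox,
                                  truncate=r / sigma_vox, mode="reflect")
    out = volume.data.copy()
    sub_mask = mask.data[sl]
    out_sub = out[sl]
    out_sub[sub_mask] = blurred[sub_mask]
    out[sl] = out_sub
    return VolumeGrid(out, volume.spacing)


def synthesize_lesion(volume: VolumeGrid, mask: LabelMask, c: float,
                      cfg: SynthesisConfig,
                      rng: np.random.Generator) -> VolumeGrid:
    """Apply the configured intensity steps for one placed candidate mask."""
    if cfg.use_gradient:
        profile = fit_gaussian_profile(mask, c, rng)
        out = apply_profile(volume, mask, profile, cfg.min_increase)
    else:
        out = flat_increase(volume, mask, c)
    if cfg.use_blur:
        out = local_blur(out, mask, cfg.blur_truncation_radius_vox,
                         cfg.blur_sigma_vox)
    return out


def synthesize_volume(volume: VolumeGrid, cord: LabelMask,
                      library: ShapeLibrary, params: ContrastParams,
                      cfg: SynthesisConfig,
                      rng: np.random.Generator) -> tuple[VolumeGrid, LabelMask]:
    """Insert a random number of synthetic lesions into a volume.

    Draws n ~ uniform{0..max_lesions_per_volume}; for each lesion selects
    a shape, augments it, places it (avoiding overlap with previously
    inserted lesions), samples a contrast factor and synthesises the
    intensity profile. Returns the modified volume and the union of
    inserted masks as the ground-truth label. Rejected placements reduce
    the realised lesion count. Deterministic given the generator state.
    """
    check_same_grid(volume, cord)
    volume.require_nonnegative()
    if not library.records:
        raise ValueError("shape library is empty")
    n = int(rng.integers(0, cfg.max_lesions_per_volume + 1))
    gt = np.zeros(volume.shape, dtype=bool)
    out = volume.copy()
    eroded = erode_sagittal(cord.data, cfg.cord_erosion_radius_vox)
    for _ in range(n):
        record = select_shape(library, rng)
        candidate = augment_shape(record, rng, cfg.p_affine_augment,
                                  cfg.p_erode, cfg.p_dilate)
        placed = place_shape(candidate, cord, target_shape=volume.shape,
                             rng=rng, avoid=gt, eroded_cord=eroded,
                             cord_erosion_radius_vox=cfg.cord_erosion_radius_vox)
        if placed is None:
            continue
        c = sample_contrast(params, rng)
        out = synthesize_lesion(out, placed, c, cfg, rng)
        gt |= placed.data
    return out, LabelMask(gt, volume.spacing)
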