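"""Synthetic straightened-cord phantoms for testing and calibration.

A phantom emulates the preprocessed T2-weighted appearance the synthesis
method assumes: a darker cord tube running along z with a mild smooth
wobble, a bright CSF sheath around it, low-intensity background, optional
additive Gaussian noise, and hyperintense lesions planted with a *flat*
multiplicative contrast drawn from a known truncated normal. Flat
planting makes the contrast-capture pipeline exact on noiseless phantoms
(the measured contrast of a planted lesion equals the planted factor),
giving every statistical module a ground-truth oracle. No attempt is
made to model MR physics (bias fields, flow artefacts, partial volume).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .contrast import ContrastParams, sample_contrast
from .grid import LabelMask, VolumeGrid, write_volume
from .morphology import dilate_sagittal, erode_sagittal
from .shapes import transform_binary_mask

__all__ = [
    "PhantomSpec",
    "make_cord_volume",
    "make_lesion_shape",
    "make_phantom_case",
    "build_phantom_dataset",
    "make_prediction_map",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the phantom generator.

    Defaults mimic the preprocessed study geometry: a (48, 48, Z) window
    at 0.5 mm isotropic spacing (Z = 200 by default; the study's median
    straightened length is longer, but the phantom is configurable), a
    cord of radius 4 mm, a 1.5 mm CSF ring, and a planting contrast law
    matching the reported lesion contrast statistics (mean 0.17, SD 0.11,
    truncated to [0.077, 1.0], the lower bound being the 20th percentile
    of that normal).
    """

    shape: tuple[int, int, int] = (48, 48, 200)
    spacing_mm: float = 0.5
    cord_radius_mm: float = 4.0
    csf_ring_thickness_mm: float = 1.5
    cord_intensity: float = 100.0
    csf_intensity: float = 180.0
    background_intensity: float = 10.0
    noise_sd: float = 2.0
    lesion_count_range: tuple[int, int] = (1, 5)
    lesion_axis_ranges_mm: tuple = ((1.0, 2.5), (1.0, 2.5), (2.0, 6.0))
    contrast_law: tuple[float, float, float, float] = (0.17, 0.11, 0.077, 1.0)
    wobble_amplitude_vox: float = 2.0

    def __post_init__(self) -> None:
        if not (self.csf_intensity > self.cord_intensity
                > self.background_intensity >= 0):
            raise ValueError("require csf > cord > background >= 0 intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        r = (self.cord_radius_mm + self.csf_ring_thickness_mm) / self.spacing_mm
        half = min(self.shape[0], self.shape[1]) / 2
        if r + self.wobble_amplitude_vox >= half:
            raise ValueError("cord + CSF ring does not fit the window")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.spacing_mm,) * 3

    def planting_params(self) -> ContrastParams:
        mu, sd, a, b = self.contrast_law
        return ContrastParams(mu_bar=mu, sigma_bar=sd, a=a, b=b, n_lesions=1)


def make_cord_volume(spec: PhantomSpec,
                     rng: np.random.Generator) -> tuple[VolumeGrid, LabelMask]:
    """Noisy tube-and-sheath volume plus the exact cord mask."""
    nx, ny, nz = spec.shape
    r_cord = spec.cord_radius_mm / spec.spacing_mm
    r_csf = r_cord + spec.csf_ring_thickness_mm / spec.spacing_mm
    cx0, cy0 = (nx - 1) / 2.0, (ny - 1) / 2.0
    # smooth axial wobble of the centreline, bounded by the configured amplitude
    amp = spec.wobble_amplitude_vox
    z = np.arange(nz)
    phx, phy = rng.uniform(0, 2 * np.pi, size=2)
    perx, pery = rng.uniform(60, 120, size=2)
    cx = cx0 + amp * np.sin(2 * np.pi * z / perx + phx)
    cy = cy0 + amp * np.sin(2 * np.pi * z / pery + phy)
    ii = np.arange(nx)[:, None, None]
    jj = np.arange(ny)[None, :, None]
    dist = np.sqrt((ii - cx[None, None, :]) ** 2 + (jj - cy[None, None, :]) ** 2)
    cord = dist <= r_cord
    csf = (dist > r_cord) & (dist <= r_csf)
    vol = np.full(spec.shape, spec.background_intensity)
    vol[csf] = spec.csf_intensity
    vol[cord] = spec.cord_intensity
    if spec.noise_sd > 0:
        vol = np.clip(vol + rng.normal(0, spec.noise_sd, size=spec.shape), 0, None)
    return VolumeGrid(vol, spec.spacing), LabelMask(cord, spec.spacing)


def make_lesion_shape(spec: PhantomSpec, rng: np.random.Generator) -> LabelMask:
    """Voxelised random ellipsoid (random semi-axes, random z rotation)
    on a compact grid; connected and non-empty by construction."""
    semi_vox = np.array([rng.uniform(lo, hi) / spec.spacing_mm
                         for lo, hi in spec.lesion_axis_ranges_mm])
    r = int(np.ceil(semi_vox.max())) + 2
    ax = np.arange(-r, r + 1)
    a, b, c = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = ((a / semi_vox[0]) ** 2 + (b / semi_vox[1]) ** 2
            + (c / semi_vox[2]) ** 2) <= 1.0
    mask[r, r, r] = True  # at least the centre voxel
    angle_z = float(rng.uniform(0, 180))
    mask = transform_binary_mask(mask, 1.0, (0.0, 0.0, angle_z))
    if not mask.any():
        mask[r, r, r] = True
    return LabelMask(mask, spec.spacing)


def _plant_lesion(volume: np.ndarray, cord: np.ndarray, gt: np.ndarray,
                  shape_mask: np.ndarray, c: float, spec: PhantomSpec,
                  rng: np.random.Generator,
                  max_attempts: int = 20) -> np.ndarray | None:
    """Place a lesion shape inside the eroded cord, away from existing
    lesions (so each planted lesion keeps an uncontaminated neighbourhood),
    and apply the flat multiplicative increase. Returns the placed mask."""
    eroded = erode_sagittal(cord, 1)
    # keep neighbourhoods clean: candidate must not meet the 5-voxel
    # sagittal dilation of existing lesions (symmetric structuring element,
    # so this also keeps existing neighbourhoods clear of the candidate)
    forbidden = dilate_sagittal(gt, 5) if gt.any() else np.zeros_like(gt)
    coords = np.argwhere(shape_mask)
    extent = coords.max(axis=0) - coords.min(axis=0) + 1
    inner = np.argwhere(eroded & ~forbidden)
    if inner.size == 0:
        return None
    for _ in range(max_attempts):
        centre = inner[int(rng.integers(len(inner)))]
        offset = centre - np.rint(coords.mean(axis=0)).astype(int)
        new = coords + offset
        inb = ((new >= 0) & (new < np.asarray(volume.shape))).all(axis=1)
        new = new[inb]
        placed = np.zeros(volume.shape, dtype=bool)
        placed[new[:, 0], new[:, 1], new[:, 2]] = True
        placed &= eroded
        if placed.sum() < 2 or np.any(placed & forbidden):
            continue
        # the dilated candidate must not touch existing lesions either
        if gt.any() and np.any(dilate_sagittal(placed, 5) & gt):
            continue
        volume[placed] *= (1.0 + c)
        return placed
    return None


def make_phantom_case(spec: PhantomSpec, rng: np.random.Generator,
                      with_lesions: bool = True):
    """One phantom: (volume, cord mask, GT lesion mask, planted records)."""
    volume, cord = make_cord_volume(spec, rng)
    gt = np.zeros(spec.shape, dtype=bool)
    planted = []
    if with_lesions:
        lo, hi = spec.lesion_count_range
        n = int(rng.integers(lo, hi + 1))
        params = spec.planting_params()
        for _ in range(n):
            shape_mask = make_lesion_shape(spec, rng)
            c = float(sample_contrast(params, rng))
            placed = _plant_lesion(volume.data, cord.data, gt,
                                   shape_mask.data, c, spec, rng)
            if placed is None:
                continue
            coords = np.argwhere(placed)
            planted.append({"contrast": c,
                            "voxels": int(placed.sum()),
                            "centroid": [float(x) for x in coords.mean(axis=0)]})
            gt |= placed
    return volume, cord, LabelMask(gt, spec.spacing), planted


def build_phantom_dataset(spec: PhantomSpec, n_with_lesions: int,
                          n_without: int, outdir: str | os.PathLike,
                          rng: np.random.Generator) -> dict:
    """Write a reproducible phantom dataset (volumes, cord masks, GT
    lesion masks) plus a JSON manifest recording every planted contrast."""
    os.makedirs(outdir, exist_ok=True)
    streams = rng.spawn(n_with_lesions + n_without)
    manifest = {"spec": {"shape": list(spec.shape),
                         "spacing_mm": spec.spacing_mm,
                         "contrast_law": list(spec.contrast_law),
                         "noise_sd": spec.noise_sd},
                "cases": []}
    for idx in range(n_with_lesions + n_without):
        with_lesions = idx < n_with_lesions
        volume, cord, gt, planted = make_phantom_case(spec, streams[idx],
                                                      with_lesions)
        stem = f"case_{idx:04d}"
        write_volume(volume, os.path.join(outdir, f"{stem}_image.nii.gz"))
        write_volume(cord, os.path.join(outdir, f"{stem}_cord.nii.gz"))
        write_volume(gt, os.path.join(outdir, f"{stem}_gt.nii.gz"))
        manifest["cases"].append({"id": stem, "with_lesions": with_lesions,
                                  "lesions": planted})
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_prediction_map(gt: LabelMask, tp_recall: float, fp_per_image: int,
                        score_law: tuple[tuple[float, float], tuple[float, float]],
                        rng: np.random.Generator,
                        cord: LabelMask | None = None) -> VolumeGrid:
    """Synthetic soft prediction map for evaluation fixtures.

    Copies a ``tp_recall`` fraction of GT components with scores drawn
    from the TP range and adds ``fp_per_image`` small spurious blobs
    (inside the cord when given) with scores from the FP range.
    """
    from scipy import ndimage as ndi
    tp_range, fp_range = score_law
    labels, n = ndi.label(gt.data, structure=np.ones((3, 3, 3), dtype=bool))
    score = np.zeros(gt.shape)
    if n > 0 and tp_recall > 0:
        k = int(round(tp_recall * n))
        chosen = rng.choice(np.arange(1, n + 1), size=k, replace=False)
        for comp in chosen:
            score[labels == comp] = rng.uniform(*tp_range)
    region = cord.data if cord is not None else np.ones(gt.shape, dtype=bool)
    candidates = np.argwhere(region & ~dilate_sagittal(gt.data, 2))
    placed_fp = 0
    attempts = 0
    while placed_fp < fp_per_image and attempts < 50 * max(fp_per_image, 1):
        attempts += 1
        if candidates.size == 0:
            break
        centre = candidates[int(rng.integers(len(candidates)))]
        blob = np.zeros(gt.shape, dtype=bool)
        lo = np.maximum(centre - 1, 0)
        hi = np.minimum(centre + 2, np.asarray(gt.shape))
        blob[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        blob &= region & ~gt.data & (score == 0)
        if not blob.any():
            continue
        score[blob] = rng.uniform(*fp_range)
        placed_fp += 1
    return VolumeGrid(np.clip(score, 0.0, 1.0), gt.spacing)
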