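"""Lesion shape library: selection, augmentation, placement.

Shapes are real (or phantom) lesion masks in straightened-cord space.
A candidate lesion is produced by drawing a shape uniformly from those
with volumes between the 10th and 90th percentiles, optionally applying
a random similarity transform (isotropic scale U(0.9, 1.1); rotations of
up to +/-5 deg about the L/R and A/P axes and +/-45 deg about the S/I
axis) and a random erosion or dilation by a radius-1 ball, translating
it to a random z position (keeping the source in-plane position), and
clipping it to the sagittally-eroded cord mask.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grid import LabelMask
from .morphology import ball, erode_sagittal

__all__ = [
    "LesionRecord",
    "ShapeLibrary",
    "split_lesions",
    "build_shape_library",
    "select_shape",
    "augment_shape",
    "place_shape",
    "save_library",
    "load_library",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(eq=False)
class LesionRecord:
    """One lesion shape with its size and geometry descriptors."""

    mask: LabelMask
    volume_mm3: float
    centroid: tuple[float, float, float]
    lengths: tuple[int, int, int]  # bounding-box extent in voxels per axis
    source_id: str = ""


@dataclass
class ShapeLibrary:
    records: list[LesionRecord]
    volume_percentiles: tuple[float, float]

    def eligible(self) -> list[LesionRecord]:
        """Records with volume in [p10, p90]; never empty (falls back to
        the full list when the filter would exclude everything)."""
        p10, p90 = self.volume_percentiles
        subset = [r for r in self.records if p10 <= r.volume_mm3 <= p90]
        return subset if subset else list(self.records)


def mask_geometry(mask: LabelMask) -> tuple[float, tuple, tuple]:
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        raise ValueError("empty mask has no geometry")
    centroid = tuple(coords.mean(axis=0))
    lengths = tuple(int(l) for l in (coords.max(axis=0) - coords.min(axis=0) + 1))
    return mask.volume_mm3(), centroid, lengths


def split_lesions(mask: LabelMask) -> list[LabelMask]:
    """Split a multi-lesion mask into 26-connected components."""
    labels, n = ndi.label(mask.data, structure=_STRUCT_26)
    return [LabelMask(labels == i, mask.spacing) for i in range(1, n + 1)]


def build_shape_library(lesion_masks, source_ids=None) -> ShapeLibrary:
    """Build a library from single-lesion masks (split multi-lesion masks
    with :func:`split_lesions` first)."""
    lesion_masks = list(lesion_masks)
    if not lesion_masks:
        raise ValueError("no lesion masks provided")
    if source_ids is None:
        source_ids = [f"lesion_{i:04d}" for i in range(len(lesion_masks))]
    records = []
    for mask, sid in zip(lesion_masks, source_ids):
        vol, centroid, lengths = mask_geometry(mask)
        records.append(LesionRecord(mask, vol, centroid, lengths, sid))
    volumes = np.array([r.volume_mm3 for r in records])
    percentiles = (float(np.percentile(volumes, 10)),
                   float(np.percentile(volumes, 90)))
    return ShapeLibrary(records, percentiles)


def select_shape(library: ShapeLibrary, rng: np.random.Generator) -> LesionRecord:
    """Uniform draw over the volume-eligible subset."""
    eligible = library.eligible()
    return eligible[int(rng.integers(len(eligible)))]


def _rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Compose per-axis rotations R = Rz @ Ry @ Rx (axis order x, y, z)."""
    ax, ay, az = (math.radians(a) for a in angles_deg)
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def transform_binary_mask(mask: np.ndarray, scale: float,
                          angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Similarity transform of a binary mask about its centroid.

    Nearest-neighbour resampling via the inverse coordinate map: output
    voxel v is set iff rint(M^{-1}(v - centroid) + centroid) lies in the
    input set. Computed only over the padded bounding box for speed.
    """
    coords_in = np.argwhere(mask)
    if coords_in.size == 0:
        return mask.copy()
    centroid = coords_in.mean(axis=0)
    rot = _rotation_matrix(angles_deg)
    inv = rot.T / scale  # inverse of scale * rot
    lo = coords_in.min(axis=0)
    hi = coords_in.max(axis=0)
    radius = np.abs(coords_in - centroid).max() if len(coords_in) else 1.0
    margin = int(math.ceil(radius * max(scale, 1.0) * 0.8)) + 3
    lo_p = np.maximum(lo - margin, 0)
    hi_p = np.minimum(hi + margin + 1, mask.shape)
    axes = [np.arange(lo_p[d], hi_p[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).astype(np.float64)
    src = np.rint((grid - centroid) @ inv.T + centroid).astype(int)
    valid = np.all((src >= 0) & (src < np.asarray(mask.shape)), axis=-1)
    out = np.zeros_like(mask)
    sub = np.zeros(valid.shape, dtype=bool)
    sv = src[valid]
    sub[valid] = mask[sv[:, 0], sv[:, 1], sv[:, 2]]
    out[lo_p[0]:hi_p[0], lo_p[1]:hi_p[1], lo_p[2]:hi_p[2]] = sub
    return out


def augment_shape(record: LesionRecord, rng: np.random.Generator,
                  p_affine: float = 0.5, p_erode: float = 0.25,
                  p_dilate: float = 0.25, max_tries: int = 10) -> LabelMask:
    """Randomly perturb a lesion shape.

    With probability ``p_affine`` an isotropic scale ~U(0.9, 1.1) and
    rotations ~(U(-5,5), U(-5,5), U(-45,45)) degrees about the x/y/z axes
    are applied about the mask centroid (nearest-neighbour resampling);
    then with probability ``p_erode`` the mask is eroded OR with
    ``p_dilate`` dilated by a radius-1 ball (mutually exclusive). If an
    augmentation empties the mask it is redrawn up to ``max_tries`` times,
    after which the unaugmented mask is returned.
    """
    base = record.mask.data
    struct = ball(1)
    for _ in range(max_tries):
        out = base
        if rng.uniform() < p_affine:
            scale = rng.uniform(0.9, 1.1)
            angles = (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(-45, 45))
            out = transform_binary_mask(out, scale, angles)
        u = rng.uniform()
        if u < p_erode:
            out = ndi.binary_erosion(out, structure=struct, border_value=0)
        elif u < p_erode + p_dilate:
            out = ndi.binary_dilation(out, structure=struct)
        if out.any():
            return LabelMask(out, record.mask.spacing)
    return record.mask.copy()


def place_shape(mask: LabelMask, cord: LabelMask,
                target_shape: tuple[int, int, int] | None = None,
                rng: np.random.Generator | None = None,
                fixed_axial: bool = False,
                cord_erosion_radius_vox: int = 1,
                avoid: np.ndarray | None = None,
                max_attempts: int = 10,
                eroded_cord: np.ndarray | None = None) -> LabelMask | None:
    """Translate a candidate mask to a random z position and clip to cord.

    The in-plane (axial) position of the source mask is kept; only the z
    coordinate of the centroid is randomised, uniformly over positions
    where the mask's z extent fits inside the target volume. The placed
    mask is intersected with the cord mask eroded by a 1-voxel disc in
    each sagittal slice (keeps CSF out of synthetic lesions). Returns
    ``None`` if no non-empty, non-overlapping placement is found within
    ``max_attempts`` (rejection, not an error).

    ``avoid`` marks voxels of previously inserted lesions; candidate
    placements intersecting it are redrawn. ``fixed_axial`` keeps the
    source z position too (no randomisation), for position-ablation use.
    """
    if cord.is_empty():
        raise ValueError("cord mask is empty")
    if target_shape is None:
        target_shape = cord.shape
    if eroded_cord is None:
        eroded_cord = erode_sagittal(cord.data, cord_erosion_radius_vox)
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        return None
    cz = coords[:, 2].astype(np.float64).mean()
    z_lo_ext = cz - coords[:, 2].min()
    z_hi_ext = coords[:, 2].max() - cz
    z_min = int(math.ceil(z_lo_ext))
    z_max = int(math.floor(target_shape[2] - 1 - z_hi_ext))
    if z_max < z_min and not fixed_axial:
        return None
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(max_attempts):
        if fixed_axial:
            dz = 0
        else:
            z_target = int(rng.integers(z_min, z_max + 1))
            dz = z_target - int(round(cz))
        new = coords.copy()
        new[:, 2] += dz
        inb = ((new >= 0) & (new < np.asarray(target_shape))).all(axis=1)
        new = new[inb]
        placed = np.zeros(target_shape, dtype=bool)
        placed[new[:, 0], new[:, 1], new[:, 2]] = True
        placed &= eroded_cord
        if not placed.any():
            if fixed_axial:
                return None
            continue
        if avoid is not None and np.any(placed & avoid):
            if fixed_axial:
                return None
            continue
        return LabelMask(placed, cord.spacing)
    return None


def save_library(library: ShapeLibrary, outdir: str | os.PathLike) -> None:
    """Serialise to a directory of NIfTI masks plus a JSON manifest."""
    from .grid import write_volume
    os.makedirs(outdir, exist_ok=True)
    manifest = []
    for i, rec in enumerate(library.records):
        fname = f"shape_{i:04d}.nii.gz"
        write_volume(rec.mask, os.path.join(outdir, fname))
        manifest.append({"file": fname, "volume_mm3": rec.volume_mm3,
                         "centroid": list(rec.centroid),
                         "lengths": list(rec.lengths),
                         "source_id": rec.source_id})
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({"shapes": manifest,
                   "volume_percentiles": list(library.volume_percentiles)}, fh,
                  indent=2)


def load_library(libdir: str | os.PathLike) -> ShapeLibrary:
    from .grid import read_volume
    with open(os.path.join(libdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    masks, ids = [], []
    for entry in manifest["shapes"]:
        masks.append(read_volume(os.path.join(libdir, entry["file"]), as_mask=True))
        ids.append(entry["source_id"])
    return build_shape_library(masks, ids)
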