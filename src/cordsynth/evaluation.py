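"""Lesion-detection and segmentation metrics.

Free-response ROC (FROC) protocol: soft score maps are binarised at an
initial threshold (0.01 or 0.5), 26-connected components are extracted
and each component receives the maximum voxel score inside it. A single
global score threshold is then swept over all component scores in the
dataset; at each threshold the dataset sensitivity (matched GT lesions /
total GT lesions) and the false positives per image (FPPI) are computed
with a greedy one-to-one IoU matching in which a predicted component is
a true positive iff its IoU with a GT component is strictly above 0.2.
The sensitivity at an FPPI level L is the best sensitivity achievable
with FPPI <= L, and the FROC score is the mean sensitivity over the five
levels {0.25, 0.5, 1, 2, 3}.

An alternative detection criterion (any non-zero overlap) and operating
point metrics at FPPI = 1 (lesion sensitivity / precision / F1, voxel
Dice and Dice restricted to overlapping lesion pairs) are also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .grid import LabelMask, VolumeGrid, check_same_grid

__all__ = [
    "ComponentSet",
    "FROCResult",
    "OperatingPoint",
    "label_components",
    "match_components",
    "froc",
    "operating_point",
    "dice",
    "epoch_iterations",
    "FPPI_LEVELS",
]

FPPI_LEVELS = (0.25, 0.5, 1.0, 2.0, 3.0)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ComponentSet:
    """Labelled 26-connected components of a binary mask, with optional
    per-component scores (max of a soft map over each component)."""

    labels: np.ndarray           # int label image, 0 = background
    n: int
    voxel_counts: np.ndarray     # (n,) voxels per component (label i -> i-1)
    scores: np.ndarray | None = None

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def label_components(mask: LabelMask | np.ndarray,
                     score_map: np.ndarray | None = None,
                     aggregation: str = "max") -> ComponentSet:
    """26-connected components; component score aggregates the soft map
    over the component (``max`` by default, ``mean`` selectable)."""
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask) > 0.5
    labels, n = ndi.label(data, structure=_STRUCT_26)
    counts = np.array([(labels == i).sum() for i in range(1, n + 1)], dtype=int)
    scores = None
    if score_map is not None and n > 0:
        agg = ndi.maximum if aggregation == "max" else ndi.mean
        scores = np.asarray(agg(score_map, labels=labels,
                                index=np.arange(1, n + 1)), dtype=float)
        scores = np.atleast_1d(scores)
    elif score_map is not None:
        scores = np.zeros(0)
    return ComponentSet(labels, int(n), counts, scores)


def _overlap_table(pred: ComponentSet, gt: ComponentSet) -> dict[tuple[int, int], int]:
    """Voxel overlap counts between every (pred, gt) component pair."""
    both = (pred.labels > 0) & (gt.labels > 0)
    if not both.any():
        return {}
    pairs, counts = np.unique(
        np.stack([pred.labels[both], gt.labels[both]]), axis=1,
        return_counts=True)
    return {(int(p), int(g)): int(c)
            for (p, g), c in zip(pairs.T, counts)}


def pair_ious(pred: ComponentSet, gt: ComponentSet) -> dict[tuple[int, int], float]:
    table = _overlap_table(pred, gt)
    out = {}
    for (p, g), inter in table.items():
        union = pred.voxel_counts[p - 1] + gt.voxel_counts[g - 1] - inter
        out[(p, g)] = inter / union
    return out


@dataclass
class Matching:
    pairs: list[tuple[int, int]]          # matched (pred_label, gt_label)
    unmatched_pred: list[int]
    unmatched_gt: list[int]
    detected_gt: set[int] = field(default_factory=set)  # any-overlap criterion


def match_components(pred: ComponentSet, gt: ComponentSet,
                     criterion: str = "iou",
                     iou_threshold: float = 0.2,
                     active_pred: set[int] | None = None) -> Matching:
    """Greedy one-to-one matching by descending IoU.

    Under ``criterion="iou"`` a pair matches iff IoU is strictly above
    ``iou_threshold``. Under ``criterion="any_overlap"`` a GT component is
    detected iff it shares at least one voxel with any predicted
    component, and a predicted component is a false positive iff it
    overlaps no GT (not one-to-one).
    """
    if active_pred is None:
        active_pred = set(range(1, pred.n + 1))
    ious = pair_ious(pred, gt)
    ious = {k: v for k, v in ious.items() if k[0] in active_pred}
    if criterion == "any_overlap":
        detected = {g for (_, g) in ious}
        fp = [p for p in sorted(active_pred)
              if not any(pp == p for (pp, _) in ious)]
        pairs = sorted({(p, g) for (p, g) in ious})
        return Matching(pairs, fp, [g for g in range(1, gt.n + 1)
                                    if g not in detected], detected)
    order = sorted(ious.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for (p, g), iou in order:
        if iou <= iou_threshold:
            break
        if p in used_p or g in used_g:
            continue
        pairs.append((p, g))
        used_p.add(p)
        used_g.add(g)
    unmatched_pred = [p for p in sorted(active_pred) if p not in used_p]
    unmatched_gt = [g for g in range(1, gt.n + 1) if g not in used_g]
    return Matching(pairs, unmatched_pred, unmatched_gt, used_g)


@dataclass
class FROCResult:
    fppi_levels: tuple[float, ...]
    sensitivity_at_level: tuple[float, ...]
    froc: float
    binarisation_threshold: float


@dataclass
class OperatingPoint:
    score_threshold: float
    fppi: float
    sensitivity: float
    precision: float
    f1: float
    dice: float
    dice_overlap_only: float


class _Instance:
    """Precomputed per-image component data for the threshold sweep."""

    def __init__(self, score_map: np.ndarray, gt_mask: np.ndarray,
                 binarisation_threshold: float, aggregation: str) -> None:
        self.pred = label_components(score_map >= binarisation_threshold,
                                     score_map, aggregation)
        self.gt = label_components(gt_mask)
        self.ious = pair_ious(self.pred, self.gt)
        self.score_map = score_map
        self.gt_mask = np.asarray(gt_mask) > 0.5

    def match_at(self, threshold: float,
                 iou_threshold: float = 0.2) -> tuple[int, int, set[int]]:
        """(n_matched_gt, n_fp, active_pred) at a component-score cut."""
        active = {p + 1 for p in range(self.pred.n)
                  if self.pred.scores[p] >= threshold}
        order = sorted(((k, v) for k, v in self.ious.items() if k[0] in active),
                       key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
        used_p: set[int] = set()
        used_g: set[int] = set()
        for (p, g), iou in order:
            if iou <= iou_threshold:
                break
            if p in used_p or g in used_g:
                continue
            used_p.add(p)
            used_g.add(g)
        return len(used_g), len(active) - len(used_p), active


def _prepare(score_maps, gt_masks, binarisation_threshold, aggregation):
    score_arrays = [m.data if isinstance(m, VolumeGrid) else np.asarray(m)
                    for m in score_maps]
    gt_arrays = [m.data if isinstance(m, LabelMask) else np.asarray(m) > 0.5
                 for m in gt_masks]
    if len(score_arrays) != len(gt_arrays) or not score_arrays:
        raise ValueError("need equal-length, non-empty score and GT lists")
    for s, g in zip(score_arrays, gt_arrays):
        if s.shape != g.shape:
            raise ValueError("score map and GT mask shapes differ")
    instances = [_Instance(s, g, binarisation_threshold, aggregation)
                 for s, g in zip(score_arrays, gt_arrays)]
    total_gt = sum(inst.gt.n for inst in instances)
    if total_gt == 0:
        raise ValueError("no GT lesions in any image: sensitivity undefined")
    return instances, total_gt


def _sweep(instances, total_gt):
    """Dataset-level sweep over all distinct component scores.

    Yields (threshold, sensitivity, fppi); includes a sentinel threshold
    above every score (zero predictions, FPPI 0).
    """
    n_images = len(instances)
    all_scores = sorted({float(s) for inst in instances
                         for s in (inst.pred.scores if inst.pred.n else [])},
                        reverse=True)
    thresholds = [math.inf] + all_scores
    for t in thresholds:
        tp = fp = 0
        for inst in instances:
            m, f, _ = inst.match_at(t)
            tp += m
            fp += f
        yield t, tp / total_gt, fp / n_images


def froc(score_maps, gt_masks, binarisation_threshold: float = 0.01,
         aggregation: str = "max",
         fppi_levels: tuple[float, ...] = FPPI_LEVELS) -> FROCResult:
    """FROC score: mean sensitivity at the FPPI levels (default
    {0.25, 0.5, 1, 2, 3}), each level taking the best sensitivity over
    thresholds with FPPI <= level."""
    instances, total_gt = _prepare(score_maps, gt_masks,
                                   binarisation_threshold, aggregation)
    points = list(_sweep(instances, total_gt))
    sens_at = []
    for level in fppi_levels:
        feasible = [s for (_, s, f) in points if f <= level]
        sens_at.append(max(feasible) if feasible else 0.0)
    return FROCResult(tuple(fppi_levels), tuple(sens_at),
                      float(np.mean(sens_at)), binarisation_threshold)


def operating_point(score_maps, gt_masks,
                    binarisation_threshold: float = 0.01,
                    aggregation: str = "max",
                    fppi_target: float = 1.0) -> OperatingPoint:
    """Metrics at the component-score threshold whose FPPI is closest to
    the target from below (ties broken towards higher sensitivity)."""
    instances, total_gt = _prepare(score_maps, gt_masks,
                                   binarisation_threshold, aggregation)
    points = list(_sweep(instances, total_gt))
    feasible = [(t, s, f) for (t, s, f) in points if f <= fppi_target]
    # closest-from-below: max fppi, then max sensitivity
    t_star, sens, fppi_val = max(feasible, key=lambda tsf: (tsf[2], tsf[1]))
    tp = fp = 0
    pred_vox = gt_vox = inter_vox = 0
    ov_pred_vox = ov_gt_vox = ov_inter_vox = 0
    for inst in instances:
        m, f, active = inst.match_at(t_star)
        tp += m
        fp += f
        active_mask = np.isin(inst.pred.labels,
                              sorted(active)) if active else np.zeros_like(
                                  inst.pred.labels, dtype=bool)
        inter = active_mask & inst.gt_mask
        pred_vox += int(active_mask.sum())
        gt_vox += int(inst.gt_mask.sum())
        inter_vox += int(inter.sum())
        # overlap-restricted Dice: keep only GT/pred components with a
        # non-zero mutual overlap at this threshold
        overlaps = [(p, g) for (p, g) in inst.ious if p in active]
        keep_pred = sorted({p for p, _ in overlaps})
        keep_gt = sorted({g for _, g in overlaps})
        pm = np.isin(inst.pred.labels, keep_pred) if keep_pred else None
        gm = np.isin(inst.gt.labels, keep_gt) if keep_gt else None
        if pm is not None and gm is not None:
            ov_pred_vox += int(pm.sum())
            ov_gt_vox += int(gm.sum())
            ov_inter_vox += int((pm & gm).sum())
    sensitivity = tp / total_gt
    n_pred = tp + fp
    precision = tp / n_pred if n_pred else 1.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    dice_all = (2 * inter_vox / (pred_vox + gt_vox)
                if pred_vox + gt_vox else 1.0)
    dice_ov = (2 * ov_inter_vox / (ov_pred_vox + ov_gt_vox)
               if ov_pred_vox + ov_gt_vox else 1.0)
    return OperatingPoint(t_star, fppi_val, sensitivity, precision, f1,
                          dice_all, dice_ov)


def dice(pred_mask: LabelMask, gt_mask: LabelMask) -> float:
    """Voxel-wise Dice 2|P∩G|/(|P|+|G|); defined as 1.0 when both empty."""
    check_same_grid(pred_mask, gt_mask)
    p, g = pred_mask.data, gt_mask.data
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def epoch_iterations(n_lesion_volumes: int, patches_per_volume: int,
                     batch_size: int) -> int:
    """Iterations per epoch when each epoch sees the lesion volumes plus
    an equal-sized group of lesion-free/synthetic volumes, each sampled
    ``patches_per_volume`` times: ceil(n * p * 2 / batch)."""
    if min(n_lesion_volumes, patches_per_volume, batch_size) < 1:
        raise ValueError("all inputs must be >= 1")
    return math.ceil(n_lesion_volumes * patches_per_volume * 2 / batch_size)
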