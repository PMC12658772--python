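"""Independent brute-force FROC oracle used by the tests.

Works on plain python voxel sets with its own breadth-first 26-connected
component search, an exhaustive sweep over every distinct component
score, and an explicitly coded greedy matcher. It shares only the
*definitions* with the package (IoU strictly above 0.2, greedy descending
IoU with ties broken by component order, dataset-pooled thresholds,
best sensitivity subject to FPPI <= level) — none of its code paths.
"""

import math
from itertools import product

NEIGHBOURS = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def components_26(voxels):
    """BFS 26-connected components of a set of voxel tuples, returned in
    ascending order of their minimum voxel (matching scanning label order)."""
    remaining = set(voxels)
    comps = []
    while remaining:
        seed = min(remaining)
        stack = [seed]
        comp = {seed}
        remaining.discard(seed)
        while stack:
            v = stack.pop()
            for d in NEIGHBOURS:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if w in remaining:
                    remaining.discard(w)
                    comp.add(w)
                    stack.append(w)
        comps.append(comp)
    comps.sort(key=min)
    return comps


def image_components(score_map, gt_mask, binarisation_threshold):
    """((voxelset, max score) predictions, gt voxelsets) for one image."""
    pred_vox = [tuple(v) for v in zip(*(score_map >= binarisation_threshold).nonzero())]
    gt_vox = [tuple(v) for v in zip(*(gt_mask > 0.5).nonzero())]
    preds = [(comp, max(score_map[v] for v in comp))
             for comp in components_26(pred_vox)]
    gts = components_26(gt_vox)
    return preds, gts


def greedy_match(active_preds, gts, iou_threshold=0.2):
    """(matched gt count, fp count) under strict-IoU greedy matching."""
    pairs = []
    for ip, (pv, _) in enumerate(active_preds):
        for ig, gv in enumerate(gts):
            inter = len(pv & gv)
            if inter:
                pairs.append((inter / len(pv | gv), ip, ig))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    mp, mg = set(), set()
    for iou, ip, ig in pairs:
        if iou <= iou_threshold:
            break
        if ip in mp or ig in mg:
            continue
        mp.add(ip)
        mg.add(ig)
    return len(mg), len(active_preds) - len(mp)


def froc_oracle(score_maps, gt_masks, binarisation_threshold,
                levels=(0.25, 0.5, 1.0, 2.0, 3.0)):
    """Exhaustive-sweep FROC plus the full (threshold, sens, fppi) list."""
    images = [image_components(s, g, binarisation_threshold)
              for s, g in zip(score_maps, gt_masks)]
    total_gt = sum(len(g) for _, g in images)
    scores = sorted({s for preds, _ in images for _, s in preds}, reverse=True)
    points = []
    for t in [math.inf] + scores:
        tp = fp = 0
        for preds, gts in images:
            active = [(v, s) for v, s in preds if s >= t]
            m, f = greedy_match(active, gts)
            tp += m
            fp += f
        points.append((t, tp / total_gt, fp / len(images)))
    sens = [max([s for _, s, f in points if f <= L], default=0.0)
            for L in levels]
    return sum(sens) / len(sens), points
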