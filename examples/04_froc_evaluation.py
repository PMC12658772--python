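"""Evaluate simulated detections with the FROC protocol.

Builds phantom ground truth, simulates an imperfect detector (80% of
lesions found with high scores, two spurious low-score blobs per image),
and computes the FROC score — the mean sensitivity at 0.25, 0.5, 1, 2 and
3 false positives per image — plus the single-threshold metrics at the
FPPI = 1 operating point.
"""

import numpy as np

from cordsynth import (PhantomSpec, froc, make_phantom_case,
                       make_prediction_map, operating_point)

spec = PhantomSpec(shape=(48, 48, 120), noise_sd=2.0)
rng = np.random.default_rng(3)

preds, gts = [], []
while len(gts) < 8:
    _, cord, gt, _ = make_phantom_case(spec, rng)
    if gt.is_empty():
        continue
    pred = make_prediction_map(gt, tp_recall=0.8, fp_per_image=2,
                               score_law=((0.6, 1.0), (0.05, 0.5)),
                               rng=rng, cord=cord)
    preds.append(pred.data)
    gts.append(gt.data)

result = froc(preds, gts, binarisation_threshold=0.01)
print("sensitivity at FPPI levels", result.fppi_levels, ":")
print("  ", [round(s, 3) for s in result.sensitivity_at_level])
print(f"FROC score (mean of the five): {result.froc:.3f}")

op = operating_point(preds, gts, binarisation_threshold=0.01)
print(f"at FPPI={op.fppi:.2f} (score threshold {op.score_threshold:.3f}): "
      f"sensitivity {op.sensitivity:.3f}, precision {op.precision:.3f}, "
      f"F1 {op.f1:.3f}, Dice {op.dice:.3f}, "
      f"Dice(overlapping pairs only) {op.dice_overlap_only:.3f}")
print("a predicted lesion counts as a true positive only when its IoU "
      "with a ground-truth lesion exceeds 0.2 strictly")
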