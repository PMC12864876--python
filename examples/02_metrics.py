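"""The detection/classification metric suite on a worked confusion quadruple.

With TP=50, TN=40, FP=5, FN=5: accuracy 0.90 means 90% of all decisions were
right; count-IoU (= CSI) 0.833 discounts the true negatives; MCC 0.798 is the
balanced correlation between truth and prediction; bookmaker informedness is
reported in its literal sensitivity+specificity form (1.798) and the standard
-1 form (0.798).
"""

import numpy as np

from pestpyramid import ConfusionCounts, bookmaker, box_iou, match_detections, \
    metric_report, roc_curve

c = ConfusionCounts(tp=50, tn=40, fp=5, fn=5)
rep = metric_report(c)
for name, val in rep.to_dict().items():
    print(f"  {name:12s} {val:.4f}")
print(f"  bm (std)     {bookmaker(c, subtract_one=True):.4f}")

print("\ngeometric box IoU of (0,0,2,2) vs (1,0,3,2):",
      f"{box_iou((0, 0, 2, 2), (1, 0, 3, 2)):.4f}  (2 shared / 6 total px)")

pred = [((10, 10, 20, 20), 0.9), ((40, 40, 50, 50), 0.8), ((0, 0, 5, 5), 0.3)]
gt = [(11, 11, 21, 21), (40, 40, 50, 50)]
m = match_detections(pred, gt, iou_threshold=0.5)
print(f"matching: tp={m.counts.tp} fp={m.counts.fp} fn={m.counts.fn}, "
      f"mean matched IoU {m.mean_iou:.3f}")

rng = np.random.default_rng(0)
scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
labels = np.array([1] * 50 + [0] * 50)
roc = roc_curve(scores, labels)
print(f"\nROC on noisy scores: AUC {roc.auc:.3f} "
      f"(1.0 = perfect ranking, 0.5 = chance)")
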