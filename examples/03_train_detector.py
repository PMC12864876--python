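"""Train the FPN detector on synthetic scenes and measure detection quality.

The detector is class-agnostic: it proposes pest boxes which the classifier
(example 04) then labels. Sensitivity is the fraction of true pests found;
mean matched IoU measures how tightly the proposed boxes fit.
"""

import numpy as np

from pestpyramid import (DetectorConfig, SceneConfig, detect,
                         generate_dataset, match_detections, train_detector)

split = generate_dataset(SceneConfig(seed=0), n_total=200, train_fraction=0.75)
cfg = DetectorConfig(hidden_width=32, learning_rate=0.3, epochs=40, seed=0)
model, costs = train_detector(split, cfg)
print(f"trained {cfg.epochs} epochs: cost {costs[0]:.2f} -> {costs[-1]:.2f}")

tp = fp = fn = 0
ious = []
for scene in split.test:
    dets = detect(scene.image, model)
    res = match_detections([(d.box, d.score) for d in dets],
                           [a.box for a in scene.annotations], 0.5)
    tp += res.counts.tp
    fp += res.counts.fp
    fn += res.counts.fn
    ious += [m[2] for m in res.matches]

print(f"held-out: sensitivity {tp / (tp + fn):.3f}  precision "
      f"{tp / (tp + fp):.3f}  mean matched IoU {np.mean(ious):.3f}")
print("(sensitivity = pests found / pests present; IoU = box overlap quality)")
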