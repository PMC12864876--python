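"""End-to-end joint run: detect pests, classify the matched crops, report.

Uses a reduced problem size so the example finishes in about half a minute;
the package default (RunConfig()) is 200 train / 50 test scenes.
"""

from pestpyramid import (ClassifierConfig, DetectorConfig, RunConfig,
                         SceneConfig, run_joint)

config = RunConfig(
    scene=SceneConfig(n_classes=3, seed=0),
    n_scenes=160, train_fraction=0.75,
    detector=DetectorConfig(hidden_width=32, epochs=40),
    classifier=ClassifierConfig(hidden_width=48, epochs=20),
    seed=0)

report = run_joint(config)
print(f"detection:  sensitivity {report.detection_sensitivity:.3f}, "
      f"precision {report.detection_precision:.3f}, "
      f"mean matched IoU {report.detection_mean_iou:.3f}")
print(f"classification (matched crops): accuracy "
      f"{report.classification_accuracy:.3f}, macro one-vs-rest accuracy "
      f"{report.classification_macro.accuracy:.3f}")
print(f"confusion matrix (rows true, cols predicted):\n{report.confusion}")
print(f"macro ROC AUC {report.roc_auc['macro']:.3f}")
print(f"objective JK = 1/accuracy + 1/IoU = {report.objective_jk:.3f} "
      f"(what the gene optimizer minimizes)")
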