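"""End-to-end orchestration: data -> detector -> classifier -> reports.

The joint run mirrors the two-stage design: the FPN proposes class-agnostic
pest boxes on each test scene, proposals are greedily matched to ground truth
at an IoU threshold, matched crops are classified, and the report aggregates
detection counts (with mean matched IoU) plus the full multiclass
classification suite (confusion matrix, one-vs-rest metrics, per-class ROC).
Spurious (unmatched) detections have no ground-truth class and are counted
only as detection false positives, never in the classification confusion.

Every run is a pure function of its ``RunConfig``; the global seed drives the
scene generator, both model initializations and the optimizer stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from .fpn import DetectorConfig, FPNDetector, detect, train_detector
from .mafvit_alstm import (ClassifierConfig, MAFViTALSTM, prepare_crop,
                           train_classifier)
from .synthetic_scenes import DatasetSplit, SceneConfig, SyntheticScene, \
    generate_dataset

logger = logging.getLogger("pestpyramid")

__all__ = ["RunConfig", "RunReport", "run_joint", "run_kfold", "run_ablation",
           "run_with_without_optimization", "evaluate_genes", "gt_crops",
           "midpoint_genes"]


@dataclass(frozen=True)
class RunConfig:
    scene: SceneConfig = SceneConfig()
    n_scenes: int = 250
    train_fraction: float = 0.8          # desk-scale default: 200 train / 50 test
    detector: DetectorConfig = DetectorConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    match_iou: float = 0.5
    output_dir: str | None = None
    seed: int = 0

    def seeded(self) -> "RunConfig":
        """Propagate the global seed into every stage."""
        return replace(
            self,
            scene=replace(self.scene, seed=self.seed),
            detector=replace(self.detector, seed=self.seed),
            classifier=replace(self.classifier,
                               seed=self.seed, n_classes=self.scene.n_classes))


@dataclass
class RunReport:
    detection_counts: M.ConfusionCounts
    detection_mean_iou: float
    detection_sensitivity: float
    detection_precision: float
    classification_macro: M.MetricReport
    classification_accuracy: float       # plain fraction correct on matched crops
    per_class: list
    confusion: np.ndarray
    roc_auc: dict                        # class id -> AUC, plus "macro"
    detector_costs: list
    classifier_costs: list
    objective_jk: float
    genes: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "detection": {
                "counts": dataclasses.asdict(self.detection_counts),
                "mean_iou": self.detection_mean_iou,
                "sensitivity": self.detection_sensitivity,
                "precision": self.detection_precision,
            },
            "classification": {
                "accuracy": self.classification_accuracy,
                "macro": self.classification_macro.to_dict(),
                "per_class": [r.to_dict() for r in self.per_class],
                "confusion": self.confusion.tolist(),
                "roc_auc": {str(k): (None if isinstance(v, float) and np.isnan(v)
                                     else v)
                            for k, v in self.roc_auc.items()},
            },
            "objective_jk": self.objective_jk,
            "detector_costs": self.detector_costs,
            "classifier_costs": self.classifier_costs,
        }
        if self.genes is not None:
            d["genes"] = self.genes
        return d


def gt_crops(scenes: list[SyntheticScene], crop_size: int = 32,
             jitter: int = 0, rng: np.random.Generator | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth crops and labels from annotated scenes.

    With ``jitter`` > 0, each annotation additionally contributes that many
    crops from randomly shifted/rescaled boxes (up to ~12% shift, 0.9-1.15x
    scale). Detector proposals are never pixel-perfect, so a classifier
    trained on exact boxes only degrades badly on matched detections; the
    jittered copies emulate proposal noise.
    """
    if jitter and rng is None:
        raise ValueError("jitter requires an rng")
    crops, labels = [], []
    for s in scenes:
        h, w = s.image.shape[:2]
        for a in s.annotations:
            crops.append(prepare_crop(s.image, a.box, crop_size))
            labels.append(a.class_id)
            x0, y0, x1, y1 = a.box
            bw, bh = x1 - x0, y1 - y0
            for _ in range(jitter):
                cx = (x0 + x1) / 2 + rng.uniform(-0.12, 0.12) * bw
                cy = (y0 + y1) / 2 + rng.uniform(-0.12, 0.12) * bh
                sc = rng.uniform(0.9, 1.15)
                box = (max(0.0, cx - bw * sc / 2), max(0.0, cy - bh * sc / 2),
                       min(float(w), cx + bw * sc / 2),
                       min(float(h), cy + bh * sc / 2))
                crops.append(prepare_crop(s.image, box, crop_size))
                labels.append(a.class_id)
    return np.asarray(crops), np.asarray(labels, dtype=int)


def _evaluate_models(detector: FPNDetector, classifier: MAFViTALSTM,
                     test_scenes: list[SyntheticScene], n_classes: int,
                     match_iou: float):
    """Detect, match, classify; returns detection + classification aggregates."""
    det_tp = det_fp = det_fn = 0
    matched_ious: list[float] = []
    y_true: list[int] = []
    probs: list[np.ndarray] = []
    for scene in test_scenes:
        dets = detect(scene.image, detector)
        gt_boxes = [a.box for a in scene.annotations]
        mr = M.match_detections([(d.box, d.score) for d in dets], gt_boxes,
                                match_iou)
        det_tp += mr.counts.tp
        det_fp += mr.counts.fp
        det_fn += mr.counts.fn
        matched_ious += [m[2] for m in mr.matches]
        matched_crops = [prepare_crop(scene.image, dets[pi].box,
                                      classifier.config.crop_size)
                         for pi, _gi, _iou in mr.matches]
        if matched_crops:
            p = classifier.predict_proba(np.asarray(matched_crops))
            probs.extend(p)
            y_true.extend(scene.annotations[gi].class_id
                          for _pi, gi, _iou in mr.matches)
    det_counts = M.ConfusionCounts(tp=det_tp, tn=0, fp=det_fp, fn=det_fn)
    return det_counts, matched_ious, np.asarray(y_true, dtype=int), \
        np.asarray(probs) if probs else np.zeros((0, n_classes))


def _assemble_report(det_counts, matched_ious, y_true, probs, n_classes,
                     det_costs, cls_costs, genes=None) -> RunReport:
    mean_iou = float(np.mean(matched_ious)) if matched_ious else 0.0
    sens = (det_counts.tp / (det_counts.tp + det_counts.fn)
            if det_counts.tp + det_counts.fn else 0.0)
    prec = (det_counts.tp / (det_counts.tp + det_counts.fp)
            if det_counts.tp + det_counts.fp else 0.0)
    y_pred = probs.argmax(axis=1) if len(probs) else np.zeros(0, dtype=int)
    conf = M.multiclass_confusion(y_true, y_pred, n_classes)
    macro = M.macro_report(conf)
    per_class = [M.metric_report(M.per_class_counts(conf, k))
                 for k in range(n_classes)]
    acc = float((y_pred == y_true).mean()) if len(y_true) else 0.0
    roc_auc: dict = {}
    aucs = []
    for k in range(n_classes):
        labels = (y_true == k).astype(int)
        try:
            roc_auc[k] = M.roc_curve(probs[:, k], labels).auc
            aucs.append(roc_auc[k])
        except M.UndefinedMetricError:
            roc_auc[k] = float("nan")
    roc_auc["macro"] = float(np.mean(aucs)) if aucs else float("nan")
    try:
        det_iou_counts = M.iou_counts(det_counts)
    except M.UndefinedMetricError:
        det_iou_counts = 0.0
    from .eigbo import objective_jk
    return RunReport(
        detection_counts=det_counts, detection_mean_iou=mean_iou,
        detection_sensitivity=sens, detection_precision=prec,
        classification_macro=macro, classification_accuracy=acc,
        per_class=per_class, confusion=conf.matrix, roc_auc=roc_auc,
        detector_costs=det_costs, classifier_costs=cls_costs,
        objective_jk=objective_jk(acc, det_iou_counts), genes=genes)


def _write_artifacts(report: RunReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    np.savetxt(out / "confusion.csv", report.confusion, fmt="%d", delimiter=",")
    pd.DataFrame({"epoch": range(len(report.detector_costs)),
                  "detector_cost": report.detector_costs}).to_csv(
        out / "detector_costs.csv", index=False)
    pd.DataFrame({"epoch": range(len(report.classifier_costs)),
                  "classifier_cost": report.classifier_costs}).to_csv(
        out / "classifier_costs.csv", index=False)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(report.detector_costs, label="detector")
        ax.plot(report.classifier_costs, label="classifier")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training cost")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "cost_curve.png", dpi=110)
        plt.close(fig)
    except Exception:                      # plotting is best-effort
        logger.warning("cost-curve plot failed", exc_info=True)


def run_joint(config: RunConfig, split: DatasetSplit | None = None) -> RunReport:
    """Full pipeline on one train/test split."""
    config = config.seeded()
    if split is None:
        logger.info("generating %d scenes", config.n_scenes)
        split = generate_dataset(config.scene, config.n_scenes,
                                 config.train_fraction)
    try:
        detector, det_costs = train_detector(split, config.detector)
    except Exception as e:
        raise RuntimeError(f"stage 'train_detector' failed: {e}") from e
    try:
        jrng = np.random.default_rng(np.random.SeedSequence((config.seed, 53)))
        crops, labels = gt_crops(split.train, config.classifier.crop_size,
                                 jitter=2, rng=jrng)
        classifier, cls_costs = train_classifier(crops, labels, config.classifier)
    except Exception as e:
        raise RuntimeError(f"stage 'train_classifier' failed: {e}") from e
    try:
        det_counts, ious, y_true, probs = _evaluate_models(
            detector, classifier, split.test, config.scene.n_classes,
            config.match_iou)
    except Exception as e:
        raise RuntimeError(f"stage 'evaluate' failed: {e}") from e
    report = _assemble_report(det_counts, ious, y_true, probs,
                              config.scene.n_classes, det_costs, cls_costs)
    if config.output_dir:
        _write_artifacts(report, config.output_dir)
    return report


def run_kfold(config: RunConfig, k: int) -> tuple[list[RunReport], pd.DataFrame]:
    """k-fold cross validation over the pooled scenes."""
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config.seeded()
    pool = generate_dataset(config.scene, config.n_scenes,
                            config.train_fraction)
    scenes = pool.train + pool.test
    folds = M.kfold_indices(len(scenes), k, seed=config.seed)
    reports, rows = [], []
    for fi, holdout in enumerate(folds):
        hold = set(int(i) for i in holdout)
        split = DatasetSplit(
            train=[s for i, s in enumerate(scenes) if i not in hold],
            test=[s for i, s in enumerate(scenes) if i in hold])
        fold_classes = {a.class_id for s in split.train for a in s.annotations}
        if len(fold_classes) < config.scene.n_classes:
            logger.warning("fold %d is missing classes %s", fi + 1,
                           set(range(config.scene.n_classes)) - fold_classes)
        rep = run_joint(replace(config, output_dir=None), split=split)
        reports.append(rep)
        rows.append({"fold": fi + 1,
                     "accuracy": rep.classification_accuracy,
                     "macro_accuracy": rep.classification_macro.accuracy,
                     "sensitivity": rep.classification_macro.sensitivity,
                     "precision": rep.classification_macro.precision,
                     "mcc": rep.classification_macro.mcc,
                     "detection_sensitivity": rep.detection_sensitivity,
                     "detection_mean_iou": rep.detection_mean_iou})
    table = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "kfold_summary.csv", index=False)
    return reports, table


_ABLATION_VARIANTS = {
    "plain_lstm": dict(use_attention=False, use_adaptive=False, use_lstm=True),
    "attention_only": dict(use_attention=True, use_adaptive=False, use_lstm=False),
    "fused_no_adaptive": dict(use_attention=True, use_adaptive=False, use_lstm=True),
    "full": dict(use_attention=True, use_adaptive=True, use_lstm=True),
}


def run_ablation(config: RunConfig) -> pd.DataFrame:
    """Classification ablation on one split: which pieces earn their keep."""
    config = config.seeded()
    split = generate_dataset(config.scene, config.n_scenes, config.train_fraction)
    crops, labels = gt_crops(split.train, config.classifier.crop_size)
    tcrops, tlabels = gt_crops(split.test, config.classifier.crop_size)
    rows = []
    for name, flags in _ABLATION_VARIANTS.items():
        ccfg = replace(config.classifier, **flags)
        try:
            model, _ = train_classifier(crops, labels, ccfg)
            pred = model.predict_proba(tcrops).argmax(axis=1)
            conf = M.multiclass_confusion(tlabels, pred, config.scene.n_classes)
            rows.append({"variant": name,
                         "accuracy": float((pred == tlabels).mean()),
                         "macro_accuracy": M.macro_report(conf).accuracy})
        except Exception as e:
            logger.warning("ablation variant %s failed: %s", name, e)
            rows.append({"variant": name, "accuracy": float("nan"),
                         "macro_accuracy": float("nan")})
    table = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ablation.csv", index=False)
    return table


# -- gene evaluation (shared by tuning and the with/without comparison) -------

def midpoint_genes() -> dict:
    """Bound midpoints of the 4-gene space: the untuned default chromosome."""
    return {"fpn_hidden": 130, "fpn_lr": 0.5, "lstm_hidden": 130, "lstm_lr": 0.5}


def evaluate_genes(split: DatasetSplit, genes: dict, *, n_classes: int = 3,
                   detector_epochs: int = 8, classifier_epochs: int = 12,
                   max_train_scenes: int = 60, max_val_scenes: int = 20,
                   match_iou: float = 0.5, seed: int = 0) -> tuple[float, float]:
    """Scaled-down train/validate with a gene vector.

    Returns (classification accuracy, count-based detection IoU) on the
    validation slice — the two terms of the JK objective.
    """
    sub = DatasetSplit(train=split.train[:max_train_scenes],
                       test=split.test[:max_val_scenes])
    dcfg = DetectorConfig(hidden_width=genes["fpn_hidden"],
                          learning_rate=genes["fpn_lr"],
                          epochs=detector_epochs, seed=seed)
    ccfg = ClassifierConfig(n_classes=n_classes,
                            hidden_width=genes["lstm_hidden"],
                            learning_rate=genes["lstm_lr"],
                            epochs=classifier_epochs, seed=seed)
    detector, _ = train_detector(sub, dcfg)
    jrng = np.random.default_rng(np.random.SeedSequence((seed, 53)))
    crops, labels = gt_crops(sub.train, ccfg.crop_size, jitter=1, rng=jrng)
    classifier, _ = train_classifier(crops, labels, ccfg)
    det_counts, _ious, y_true, probs = _evaluate_models(
        detector, classifier, sub.test, n_classes, match_iou)
    acc = float((probs.argmax(axis=1) == y_true).mean()) if len(y_true) else 0.0
    try:
        iou = M.iou_counts(det_counts)
    except M.UndefinedMetricError:
        iou = 0.0
    return acc, iou


def run_with_without_optimization(
        config: RunConfig, *, population: int = 6, iterations: int = 8,
        detector_epochs: int = 6, classifier_epochs: int = 8,
        max_train_scenes: int = 40, max_val_scenes: int = 15) -> dict:
    """Paired comparison: bound-midpoint genes vs EIGBO-RE-tuned genes.

    Both chromosomes are evaluated with the identical scaled-down budget on
    the identical split, so the objective difference isolates the tuning.
    """
    from .eigbo import objective_jk, tune_pipeline

    config = config.seeded()
    split = generate_dataset(config.scene, config.n_scenes, config.train_fraction)
    budget = dict(detector_epochs=detector_epochs,
                  classifier_epochs=classifier_epochs,
                  max_train_scenes=max_train_scenes,
                  max_val_scenes=max_val_scenes)
    default = midpoint_genes()
    acc_d, iou_d = evaluate_genes(split, default, n_classes=config.scene.n_classes,
                                  seed=config.seed, **budget)
    tuned, trace = tune_pipeline(split, n_classes=config.scene.n_classes,
                                 population=population, iterations=iterations,
                                 variant="eigbo_re", seed=config.seed, **budget)
    acc_t, iou_t = evaluate_genes(split, tuned, n_classes=config.scene.n_classes,
                                  seed=config.seed, **budget)
    result = {
        "default_genes": default,
        "tuned_genes": tuned,
        "default": {"accuracy": acc_d, "iou": iou_d,
                    "objective_jk": objective_jk(acc_d, iou_d)},
        "tuned": {"accuracy": acc_t, "iou": iou_t,
                  "objective_jk": objective_jk(acc_t, iou_t)},
        "objective_delta": objective_jk(acc_t, iou_t) - objective_jk(acc_d, iou_d),
        "trace_best_fitness": trace.best_fitness,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "with_without_optimization.json").write_text(
            json.dumps(result, indent=1))
    return result
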