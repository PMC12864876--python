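"""Detection/classification metric suite.

All scalar metrics are defined on a TP/TN/FP/FN quadruple:

    accuracy     (TP+TN) / (TP+TN+FP+FN)
    iou (counts) TP / (TP+FP+FN)            -- identical to CSI by definition
    sensitivity  TP / (TP+FN)
    precision    TP / (TP+FP)
    fnr          FN / (TP+FN)               -- complement of sensitivity
    npv          TN / (TN+FN)
    mcc          (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    bookmaker    sensitivity + specificity  (literal form; the standard
                 informedness subtracts 1, selectable via ``subtract_one``)

plus the geometric box IoU used for detection matching, a grouped-threshold
ROC with trapezoidal AUC, one-vs-rest multiclass reductions, and seeded
k-fold index partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "MulticlassConfusion", "RocCurve",
           "UndefinedMetricError", "accuracy", "iou_counts", "sensitivity",
           "precision", "fnr", "npv", "csi", "mcc", "specificity", "bookmaker",
           "metric_report", "box_iou", "match_detections", "multiclass_confusion",
           "per_class_counts", "macro_report", "micro_counts", "roc_curve",
           "kfold_indices"]


class UndefinedMetricError(ValueError):
    """A ratio metric was requested with a zero denominator."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric '{metric}' undefined: zero denominator")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    iou: float
    sensitivity: float
    precision: float
    fnr: float
    npv: float
    csi: float
    mcc: float
    specificity: float
    bm: float

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(name)
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def iou_counts(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn, "iou")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def fnr(c: ConfusionCounts) -> float:
    return _ratio(c.fn, c.tp + c.fn, "fnr")


def npv(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fn, "npv")


def csi(c: ConfusionCounts) -> float:
    # critical success index: same ratio as count-based IoU
    return _ratio(c.tp, c.tp + c.fn + c.fp, "csi")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def mcc(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("mcc")
    tp, tn, fp_, fn_ = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom2 = (tp + fp_) * (tp + fn_) * (tn + fp_) * (tn + fn_)
    if denom2 == 0:
        return 0.0  # any zero marginal: conventional value
    return (tp * tn - fp_ * fn_) / np.sqrt(denom2)


def bookmaker(c: ConfusionCounts, subtract_one: bool = False) -> float:
    """Bookmaker informedness: sensitivity + specificity [- 1]."""
    val = sensitivity(c) + specificity(c)
    return val - 1.0 if subtract_one else val


def metric_report(c: ConfusionCounts, strict: bool = False) -> MetricReport:
    """All scalar metrics at once.

    With ``strict`` any undefined metric raises; otherwise it contributes 0.
    """
    def safe(fn, *a):
        try:
            return fn(c, *a)
        except UndefinedMetricError:
            if strict:
                raise
            return 0.0

    return MetricReport(accuracy=safe(accuracy), iou=safe(iou_counts),
                        sensitivity=safe(sensitivity), precision=safe(precision),
                        fnr=safe(fnr), npv=safe(npv), csi=safe(csi),
                        mcc=safe(mcc), specificity=safe(specificity),
                        bm=safe(bookmaker))


# -- geometric IoU & detection matching ---------------------------------------

def box_iou(a, b) -> float:
    """Intersection over union of two half-open pixel boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a == 0 or area_b == 0:
        warnings.warn("degenerate zero-area box in IoU", stacklevel=2)
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(0.0, iw) * max(0.0, ih)
    return inter / (area_a + area_b - inter)


@dataclass(frozen=True)
class MatchResult:
    counts: ConfusionCounts
    mean_iou: float                      # mean IoU over matched (TP) pairs
    matches: tuple                       # (pred_index, gt_index, iou) triples


def match_detections(pred: list, gt: list, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy score-ordered matching of predicted boxes to ground truth.

    ``pred`` is a list of ``(box, score)``; each ground-truth box is consumed
    by at most one prediction. A pair with IoU >= threshold is a TP; leftover
    predictions are FP, leftover ground truth FN. TN is structurally 0 for
    detection.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(range(len(pred)), key=lambda i: -pred[i][1])
    taken = [False] * len(gt)
    matches = []
    for pi in order:
        box = pred[pi][0]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gt):
            if taken[j]:
                continue
            v = box_iou(box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            matches.append((pi, best_j, best_iou))
    tp = len(matches)
    counts = ConfusionCounts(tp=tp, tn=0, fp=len(pred) - tp, fn=len(gt) - tp)
    mean_iou = float(np.mean([m[2] for m in matches])) if matches else 0.0
    return MatchResult(counts=counts, mean_iou=mean_iou, matches=tuple(matches))


# -- multiclass ---------------------------------------------------------------

@dataclass(frozen=True)
class MulticlassConfusion:
    matrix: np.ndarray                   # (K, K), rows true, cols predicted

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]


def multiclass_confusion(true_labels, pred_labels, n_classes: int) -> MulticlassConfusion:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (t, p), 1)
    return MulticlassConfusion(matrix=m)


def per_class_counts(m: MulticlassConfusion, k: int) -> ConfusionCounts:
    """One-vs-rest reduction of class ``k``."""
    mat = m.matrix
    tp = int(mat[k, k])
    fn = int(mat[k].sum() - tp)
    fp = int(mat[:, k].sum() - tp)
    tn = int(mat.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def macro_report(m: MulticlassConfusion) -> MetricReport:
    """Unweighted mean of per-class one-vs-rest metrics."""
    reports = [metric_report(per_class_counts(m, k)).to_dict()
               for k in range(m.n_classes)]
    return MetricReport(**{f: float(np.mean([r[f] for r in reports]))
                           for f in reports[0]})


def micro_counts(m: MulticlassConfusion) -> ConfusionCounts:
    """Summed one-vs-rest counts (micro aggregation)."""
    agg = dict(tp=0, tn=0, fp=0, fn=0)
    for k in range(m.n_classes):
        c = per_class_counts(m, k)
        for f in agg:
            agg[f] += getattr(c, f)
    return ConfusionCounts(**agg)


# -- ROC ----------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    """ROC over descending unique score thresholds, ties grouped; trapezoid AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("roc_curve (single-class labels)")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    uniq_mask = np.concatenate([np.diff(s) != 0, [True]])  # last of each tie group
    tps = np.cumsum(y == 1)[uniq_mask]
    fps = np.cumsum(y == 0)[uniq_mask]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s[uniq_mask]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


# -- k-fold -------------------------------------------------------------------

def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffle of [0, n) split into k folds with sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    idx = np.arange(n)
    np.random.default_rng(seed).shuffle(idx)
    return [fold.copy() for fold in np.array_split(idx, k)]
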