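"""Metric formulas against independent oracles (plain arithmetic, sklearn)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pestpyramid import metrics as M
from pestpyramid.metrics import ConfusionCounts


class TestScalarMetrics:
    @pytest.mark.parametrize("fn,counts,expected", [
        (M.accuracy, (1, 1, 0, 0), 1.0),
        (M.accuracy, (0, 0, 1, 1), 0.0),
        (M.accuracy, (50, 40, 5, 5), 0.9),
        (M.iou_counts, (50, 40, 5, 5), 50 / 60),
        (M.sensitivity, (50, 40, 5, 5), 50 / 55),
        (M.precision, (50, 40, 5, 5), 50 / 55),
        (M.npv, (50, 40, 5, 5), 40 / 45),
        (M.csi, (50, 40, 5, 5), 50 / 60),
        (M.mcc, (1, 1, 0, 0), 1.0),
        (M.mcc, (1, 1, 1, 1), 0.0),
        (M.mcc, (50, 40, 5, 5), 1975 / 2475),
    ])
    def test_worked_examples(self, fn, counts, expected):
        assert fn(ConfusionCounts(*counts)) == pytest.approx(expected, abs=1e-12)

    def test_bookmaker_literal_and_standard(self):
        c = ConfusionCounts(50, 40, 5, 5)
        assert M.bookmaker(c) == pytest.approx(50 / 55 + 40 / 45, abs=1e-12)
        assert M.bookmaker(c, subtract_one=True) == pytest.approx(
            50 / 55 + 40 / 45 - 1, abs=1e-12)
        perfect = ConfusionCounts(1, 1, 0, 0)
        assert M.bookmaker(perfect) == 2.0
        assert M.bookmaker(perfect, subtract_one=True) == 1.0

    def test_undefined_denominators_raise_named_error(self):
        with pytest.raises(M.UndefinedMetricError, match="sensitivity"):
            M.sensitivity(ConfusionCounts(0, 5, 3, 0))
        with pytest.raises(M.UndefinedMetricError, match="accuracy"):
            M.accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 20, size=4)
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            assert M.mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-10)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_complement_and_csi_identities(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        if tp + fn > 0:
            assert M.sensitivity(c) + M.fnr(c) == pytest.approx(1.0, abs=1e-12)
        if tp + fp + fn > 0:
            assert M.csi(c) == M.iou_counts(c)
            if c.total > 0:
                assert M.accuracy(c) >= M.csi(c) - 1e-12
        if c.total > 0:
            assert -1.0 - 1e-12 <= M.mcc(c) <= 1.0 + 1e-12


class TestBoxIoU:
    def test_identical_and_disjoint(self):
        assert M.box_iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0
        assert M.box_iou((0, 0, 2, 2), (5, 5, 8, 8)) == 0.0

    def test_known_overlap_equals_pixel_counting(self):
        # (0,0,2,2) vs (1,0,3,2): 2 shared pixels of 6 total on the grid
        assert M.box_iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_degenerate_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert M.box_iou((0, 0, 0, 2), (0, 0, 2, 2)) == 0.0

    @given(st.tuples(*[st.integers(0, 20)] * 4), st.tuples(*[st.integers(0, 20)] * 4))
    def test_symmetry(self, a, b):
        a = (min(a[0], a[2]), min(a[1], a[3]), max(a[0], a[2]) + 1, max(a[1], a[3]) + 1)
        b = (min(b[0], b[2]), min(b[1], b[3]), max(b[0], b[2]) + 1, max(b[1], b[3]) + 1)
        assert M.box_iou(a, b) == M.box_iou(b, a)
        assert M.box_iou(a, a) == 1.0


class TestMatching:
    def test_perfect_predictions(self):
        gt = [(0, 0, 4, 4), (10, 10, 14, 14)]
        res = M.match_detections([(g, 1.0) for g in gt], gt, 0.5)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (2, 0, 0)
        assert res.mean_iou == 1.0

    def test_empty_predictions_all_missed(self):
        res = M.match_detections([], [(0, 0, 4, 4)], 0.5)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (0, 0, 1)

    def test_low_iou_pair_counts_as_fp_and_fn(self):
        res = M.match_detections([((0, 0, 2, 2), 0.9)], [(1, 0, 3, 2)], 0.5)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (0, 1, 1)

    def test_each_gt_matched_at_most_once(self):
        gt = [(0, 0, 4, 4)]
        preds = [((0, 0, 4, 4), 0.9), ((0, 0, 4, 4), 0.8)]
        res = M.match_detections(preds, gt, 0.5)
        assert (res.counts.tp, res.counts.fp) == (1, 1)


class TestMulticlass:
    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 1, 0]
        m = M.multiclass_confusion(y, y, 3)
        assert np.array_equal(m.matrix, np.diag([2, 2, 1]))
        assert M.macro_report(m).accuracy == 1.0

    def test_binary_reduction_matches_direct_counts(self):
        yt = [0, 0, 1, 1, 1]
        yp = [0, 1, 1, 1, 0]
        m = M.multiclass_confusion(yt, yp, 2)
        c = M.per_class_counts(m, 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)

    def test_per_class_counts_sum_to_total(self, rng):
        yt = rng.integers(0, 3, 30)
        yp = rng.integers(0, 3, 30)
        m = M.multiclass_confusion(yt, yp, 3)
        for k in range(3):
            c = M.per_class_counts(m, k)
            # brute-force tally
            tp = int(((yt == k) & (yp == k)).sum())
            fn = int(((yt == k) & (yp != k)).sum())
            fp = int(((yt != k) & (yp == k)).sum())
            assert (c.tp, c.fn, c.fp) == (tp, fn, fp)
            assert c.total == 30

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            M.multiclass_confusion([0, 3], [0, 1], 3)


class TestRoc:
    def test_perfect_and_inverted_separation(self):
        roc = M.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        roc = M.roc_curve([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert roc.auc == 0.0

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        roc = M.roc_curve(scores, labels)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_auc_equals_mann_whitney_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = np.round(rng.normal(size=60), 1)   # force ties
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        auc = M.roc_curve(scores, labels).auc
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = (pos[:, None] > neg[None]).sum() + 0.5 * (pos[:, None] == neg[None]).sum()
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a1 = M.roc_curve(scores, labels).auc
        a2 = M.roc_curve(np.exp(2 * scores) + 5, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(M.UndefinedMetricError):
            M.roc_curve([0.1, 0.9], [1, 1])


class TestKfold:
    @pytest.mark.parametrize("n,k,sizes", [(10, 5, {2}), (10, 3, {4, 3})])
    def test_fold_sizes(self, n, k, sizes):
        folds = M.kfold_indices(n, k, seed=0)
        assert {len(f) for f in folds} == sizes

    @given(n=st.integers(2, 60), k=st.integers(2, 10), seed=st.integers(0, 5))
    def test_folds_partition_index_range(self, n, k, seed):
        if k > n:
            with pytest.raises(ValueError):
                M.kfold_indices(n, k, seed)
            return
        folds = M.kfold_indices(n, k, seed)
        flat = np.concatenate(folds)
        assert sorted(flat.tolist()) == list(range(n))

    def test_seed_determinism(self):
        f1 = M.kfold_indices(20, 4, seed=9)
        f2 = M.kfold_indices(20, 4, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
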