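import numpy as np
import pytest
from hypothesis import given, strategies as st

from slicegru.ensemble import (
    CVSplit,
    FusionWeights,
    PredictionScore,
    UndefinedMetricError,
    compute_metrics,
    evaluate_scores,
    fuse,
    grid_search_weights,
    make_folds,
    null_auc_band,
    prune_cnns,
    roc_auc,
    simplex_grid,
)


class TestPrune:
    def test_threshold_comparison(self):
        assert prune_cnns({1: 0.9, 2: 0.5, 3: 0.7}, 0.55) == [1, 3]

    def test_all_below_keeps_best(self):
        assert prune_cnns({1: 0.3, 2: 0.45, 3: 0.41}, 0.55) == [2]

    def test_zero_threshold_keeps_all(self):
        assert prune_cnns({1: 0.2, 2: 0.0, 3: 0.9}, 0.0) == [1, 2, 3]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prune_cnns({}, 0.5)


def score(sid, source, p):
    return PredictionScore(subject_id=sid, source=source, probs=np.array(p))


class TestFuse:
    def test_degenerate_weights_pick_one_view(self):
        scores = {
            "axial": score("s1", "axial", [0.8, 0.2]),
            "sagittal": score("s1", "sagittal", [0.6, 0.4]),
            "coronal": score("s1", "coronal", [0.5, 0.5]),
        }
        out = fuse(scores, FusionWeights(1.0, 0.0, 0.0))
        np.testing.assert_allclose(out.probs, [0.8, 0.2])

    def test_identical_scores_fixed_point(self):
        scores = {v: score("s1", v, [0.7, 0.3]) for v in ("axial", "sagittal", "coronal")}
        out = fuse(scores, FusionWeights(0.2, 0.5, 0.3))
        np.testing.assert_allclose(out.probs, [0.7, 0.3], atol=1e-15)

    def test_weighted_sum_oracle(self):
        scores = {
            "axial": score("s1", "axial", [0.8, 0.2]),
            "sagittal": score("s1", "sagittal", [0.6, 0.4]),
            "coronal": score("s1", "coronal", [0.5, 0.5]),
        }
        out = fuse(scores, FusionWeights(0.5, 0.3, 0.2))
        np.testing.assert_allclose(out.probs, [0.68, 0.32], atol=1e-12)
        assert out.source == "fused"

    def test_missing_view_rejected(self):
        with pytest.raises(ValueError):
            fuse({"axial": score("s1", "axial", [1.0, 0.0])}, FusionWeights(1, 0, 0))

    def test_invalid_probability_vectors_rejected(self):
        with pytest.raises(ValueError):
            PredictionScore("s1", "axial", np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            FusionWeights(0.5, 0.6, 0.2)
        with pytest.raises(ValueError):
            FusionWeights(-0.2, 0.6, 0.6)


class TestGridSearch:
    def test_simplex_sizes(self):
        assert len(simplex_grid(0.5)) == 6  # compositions of 2 into 3 parts
        assert len(simplex_grid(0.1)) == 66

    def test_perfect_view_reaches_full_accuracy(self, rng):
        labels = np.array([0, 1] * 10)
        perfect = np.column_stack([1.0 - labels, labels]).astype(float)
        chance = np.full((20, 2), 0.5)
        weights, acc = grid_search_weights({"axial": perfect, "sagittal": chance, "coronal": chance}, labels)
        assert acc == 1.0

    def test_full_tie_returns_uniform(self):
        labels = np.array([0, 1, 0, 1])
        same = np.column_stack([[0.6, 0.4, 0.7, 0.2], [0.4, 0.6, 0.3, 0.8]])
        weights, _ = grid_search_weights({v: same for v in ("axial", "sagittal", "coronal")}, labels, step=0.1)
        # every triple fuses to the same scores; tie-break picks the most uniform
        assert sorted([weights.w_axial, weights.w_sagittal, weights.w_coronal]) == [0.3, 0.3, 0.4]

    def test_fused_at_least_as_good_as_each_view(self, rng):
        labels = rng.integers(0, 2, 30)
        views = {}
        for v in ("axial", "sagittal", "coronal"):
            p1 = rng.random(30)
            views[v] = np.column_stack([1 - p1, p1])
        _, fused_acc = grid_search_weights(views, labels)
        for v in views:
            single = float((views[v].argmax(axis=1) == labels).mean())
            assert fused_acc >= single  # the grid contains the degenerate corners

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            grid_search_weights({v: np.zeros((0, 2)) for v in ("axial", "sagittal", "coronal")}, np.array([]))


class TestFolds:
    def test_balanced_partition(self):
        labels = np.repeat([0, 1], 50)
        split = make_folds(labels, k=10, seed=3)
        sizes = [int((split.fold_of == f).sum()) for f in range(10)]
        assert sizes == [10] * 10

    def test_stratification_within_one_subject(self):
        labels = np.repeat([0, 1], [60, 40])
        split = make_folds(labels, k=10, seed=0)
        for f in range(10):
            fold_labels = labels[split.fold_of == f]
            assert abs((fold_labels == 1).sum() - 4) <= 1

    def test_deterministic_under_seed(self):
        labels = np.repeat([0, 1], 30)
        a = make_folds(labels, k=10, seed=7)
        b = make_folds(labels, k=10, seed=7)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.repeat([0, 1], [50, 5]), k=10)

    def test_rotation_roles(self):
        labels = np.repeat([0, 1], 20)
        split = make_folds(labels, k=10, seed=1)
        seen_test = np.zeros(40, dtype=int)
        for r in range(10):
            train, val, test = split.rotation(r)
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.intersect1d(val, test)) == 0
            assert len(train) + len(val) + len(test) == 40
            seen_test[test] += 1
        assert (seen_test == 1).all()  # each subject tested exactly once


class TestMetrics:
    def test_perfection(self):
        labels = np.array([0, 1, 0, 1])
        scores = np.column_stack([1 - labels, labels]).astype(float)
        rep = compute_metrics(scores, labels)
        assert rep.acc == rep.sen == rep.spe == 1.0

    def test_confusion_table_counts(self):
        # 2 TP, 1 FN, 3 TN, 1 FP
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        preds = np.array([1, 1, 0, 0, 0, 0, 1])
        scores = np.column_stack([1 - preds, preds]).astype(float)
        rep = compute_metrics(scores, labels)
        assert rep.sen == pytest.approx(2 / 3)
        assert rep.spe == pytest.approx(3 / 4)
        assert rep.acc == pytest.approx(5 / 7)

    def test_undefined_flags(self):
        labels = np.ones(4, dtype=int)
        scores = np.column_stack([np.zeros(4), np.ones(4)])
        rep = compute_metrics(scores, labels)
        assert rep.spe is None
        assert rep.sen == 1.0

    @given(st.integers(1, 20), st.integers(1, 20), st.integers(0, 123456))
    def test_acc_identity_on_random_confusions(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        preds = rng.integers(0, 2, n_pos + n_neg)
        scores = np.column_stack([1 - preds, preds]).astype(float)
        rep = compute_metrics(scores, labels)
        lhs = rep.acc * (n_pos + n_neg)
        rhs = rep.sen * n_pos + rep.spe * n_neg
        assert lhs == pytest.approx(rhs, abs=1e-9)


def pair_counting_auc(scores, labels):
    """Independent oracle: enumerate every (positive, negative) pair."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        labels = np.array([1, 1, 0, 0])
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels)
        assert auc == 1.0

    def test_anti_separation(self):
        labels = np.array([1, 1, 0, 0])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert auc == 0.0

    def test_small_example_pair_count(self):
        labels = np.array([1, 1, 0, 0])
        _, auc = roc_auc(np.array([0.9, 0.4, 0.6, 0.1]), labels)
        assert auc == pytest.approx(3 / 4, abs=1e-15)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        roc, _ = roc_auc(rng.random(25), labels)
        np.testing.assert_allclose(roc[0], [0, 0])
        np.testing.assert_allclose(roc[-1], [1, 1])
        assert (np.diff(roc[:, 0]) >= 0).all()
        assert (np.diff(roc[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([0.4, 0.6]), np.array([1, 1]))

    def test_null_band_brackets_half(self):
        lo, hi = null_auc_band(20, 20, n_draws=400, seed=0)
        assert lo < 0.5 < hi
        assert 0.2 < lo < 0.45 and 0.55 < hi < 0.8

    def test_report_combines_metrics_and_auc(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.6, 0.4], [0.3, 0.7], [0.2, 0.8]])
        rep = evaluate_scores(scores, labels)
        assert rep.acc == 1.0 and rep.auc == 1.0 and rep.roc is not None
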