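import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcgnn import (
    ConfusionCounts,
    ResamplingPolicy,
    apply_resampling,
    compute_auc,
    compute_confusion,
    compute_metrics,
    stratified_kfold,
)


def auc_pairwise_oracle(y, scores, positive_class=1):
    """O(n^2) Mann-Whitney count: wins + half-ties over all
    positive/negative pairs."""
    pos = [s for s, t in zip(scores, y) if t == positive_class]
    neg = [s for s, t in zip(scores, y) if t != positive_class]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_divisible_case_exact(self):
        labels = np.array([1] * 60 + [0] * 40)
        plan = stratified_kfold(labels, n_folds=10, seed=0)
        for f in range(10):
            test = plan.test_indices(f)
            assert np.sum(labels[test] == 1) == 6
            assert np.sum(labels[test] == 0) == 4

    def test_partition(self):
        labels = np.array([0, 1] * 37)
        plan = stratified_kfold(labels, n_folds=10, seed=3)
        all_idx = np.concatenate([plan.test_indices(f) for f in range(10)])
        assert sorted(all_idx) == list(range(74))

    def test_study_cohort_fold_counts(self):
        # 821 patients / 765 controls: fold class counts must be the
        # floor/ceiling of 82.1 and 76.5
        labels = np.array([1] * 821 + [0] * 765)
        plan = stratified_kfold(labels, n_folds=10, seed=1)
        pos = [int(np.sum(labels[plan.test_indices(f)] == 1))
               for f in range(10)]
        neg = [int(np.sum(labels[plan.test_indices(f)] == 0))
               for f in range(10)]
        assert set(pos) <= {82, 83} and sum(pos) == 821
        assert set(neg) <= {76, 77} and sum(neg) == 765

    def test_deterministic_given_seed(self):
        labels = np.array([0, 1] * 30)
        p1 = stratified_kfold(labels, seed=5)
        p2 = stratified_kfold(labels, seed=5)
        p3 = stratified_kfold(labels, seed=6)
        assert np.array_equal(p1.assignments, p2.assignments)
        assert not np.array_equal(p1.assignments, p3.assignments)

    def test_small_class_errors(self):
        labels = np.array([0] * 50 + [1] * 5)
        with pytest.raises(ValueError):
            stratified_kfold(labels, n_folds=10, seed=0)


class TestResampling:
    def test_upsample_duplicates_minority(self):
        ids = np.arange(16)
        labels = np.array([0] * 10 + [1] * 6)
        out = apply_resampling(ids, labels, ResamplingPolicy("upsample",
                                                             seed=0))
        out_labels = labels[out]
        assert np.sum(out_labels == 0) == 10
        assert np.sum(out_labels == 1) == 10
        # every original subject still present
        assert set(ids) <= set(out)
        # additions are copies of existing minority subjects
        extra = [i for i in out if list(out).count(i) > 1]
        assert all(labels[i] == 1 for i in extra)

    def test_downsample_subsets_majority(self):
        ids = np.arange(16)
        labels = np.array([0] * 10 + [1] * 6)
        out = apply_resampling(ids, labels, ResamplingPolicy("downsample",
                                                             seed=0))
        assert len(out) == 12
        assert len(set(out)) == 12          # no duplication
        assert set(out) <= set(ids)          # subset of originals
        assert np.sum(labels[out] == 0) == 6

    def test_balanced_input_fixed_point(self):
        ids = np.arange(10)
        labels = np.array([0] * 5 + [1] * 5)
        for mode in ("upsample", "downsample"):
            out = apply_resampling(ids, labels,
                                   ResamplingPolicy(mode, seed=1))
            assert sorted(out) == sorted(ids)

    def test_none_is_identity(self):
        ids = np.arange(7)
        labels = np.array([0, 0, 0, 0, 1, 1, 1])
        out = apply_resampling(ids, labels, ResamplingPolicy("none"))
        assert np.array_equal(out, ids)

    def test_deterministic_given_seed(self):
        ids = np.arange(30)
        labels = np.array([0] * 20 + [1] * 10)
        p = ResamplingPolicy("upsample", seed=9)
        assert np.array_equal(apply_resampling(ids, labels, p),
                              apply_resampling(ids, labels, p))


class TestConfusionAndMetrics:
    def test_worked_example(self):
        truth = [1, 1, 1, 1, 1, 0, 0, 0]
        pred = [1, 1, 1, 0, 0, 0, 0, 1]
        c = compute_confusion(truth, pred)
        assert (c.TP, c.FN, c.TN, c.FP) == (3, 2, 2, 1)
        acc, sen, spe = compute_metrics(c)
        assert acc == pytest.approx(0.625)
        assert sen == pytest.approx(0.6)
        assert spe == pytest.approx(2 / 3)

    def test_perfect_and_inverted(self):
        truth = np.array([1, 1, 0, 0, 0])
        c = compute_confusion(truth, truth)
        assert c.FP == c.FN == 0
        assert compute_metrics(c) == (1.0, 1.0, 1.0)
        c_inv = compute_confusion(truth, 1 - truth)
        assert (c_inv.TP, c_inv.TN) == (0, 0)
        assert (c_inv.FP, c_inv.FN) == (3, 2)

    def test_zero_sensitivity(self):
        c = ConfusionCounts(TP=0, TN=3, FP=0, FN=5)
        _, sen, _ = compute_metrics(c)
        assert sen == 0.0

    def test_undefined_metrics_are_none(self):
        _, sen, spe = compute_metrics(ConfusionCounts(0, 4, 1, 0))
        assert sen is None and spe is not None
        _, sen, spe = compute_metrics(ConfusionCounts(2, 0, 0, 1))
        assert spe is None and sen is not None

    def test_bad_labels_error(self):
        with pytest.raises(ValueError):
            compute_confusion([0, 2], [0, 1])

    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(0, 500)))
    @settings(max_examples=200, deadline=None)
    def test_accuracy_identity(self, counts):
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp, tn, fp, fn)
        if c.total == 0:
            return
        acc, sen, spe = compute_metrics(c)
        p, n = tp + fn, tn + fp
        if sen is not None and spe is not None:
            assert acc * (p + n) == pytest.approx(sen * p + spe * n)


class TestRunCVErrors:
    def test_training_failure_names_fold(self, monkeypatch, small_cohort):
        import fcgnn.evaluation as ev

        def boom(*a, **k):
            raise ValueError("synthetic training failure")

        monkeypatch.setattr(ev, "train_base", boom)
        cohort, _ = small_cohort
        from fcgnn import EnsembleConfig, OptimizerConfig

        with pytest.raises(ValueError, match="fold 0: synthetic"):
            ev.run_cv(cohort, EnsembleConfig(),
                      OptimizerConfig(epochs=1, seed=0), fold_seed=0)


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert compute_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # induce some ties
            assert compute_auc(y, scores) == pytest.approx(
                auc_pairwise_oracle(y, scores), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_auc([1, 1, 1], [0.1, 0.5, 0.9])
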