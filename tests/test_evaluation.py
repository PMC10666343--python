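import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import ncbind as nb
from ncbind.evaluation import stratified_fold_indices
from ncbind.exceptions import ShapeError, TrainingError, UndefinedMetricError


def rank_statistic_auc(labels, scores):
    """Mann–Whitney AUC with tied scores counted one half (independent
    oracle for the trapezoidal ROC integration)."""
    labels = np.asarray(labels)
    ranks = stats.rankdata(scores)  # midranks handle ties
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusion:
    def test_perfect_agreement(self):
        c = nb.confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_total_disagreement(self):
        c = nb.confusion([1, 0], [0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 1)

    def test_counts_partition_the_samples(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 1000)
        p = rng.integers(0, 2, 1000)
        assert nb.confusion(y, p).total == 1000

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            nb.confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = nb.metrics(nb.ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted_classifier(self):
        m = nb.metrics(nb.ConfusionCounts(tp=0, tn=0, fp=5, fn=5))
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_hand_computed_mixed_case(self):
        m = nb.metrics(nb.ConfusionCounts(tp=3, fn=1, tn=2, fp=2))
        assert m.sn == pytest.approx(0.75)
        assert m.sp == pytest.approx(0.5)
        assert m.acc == pytest.approx(0.625)
        assert m.mcc == pytest.approx(4 / np.sqrt(240))

    def test_mcc_zero_denominator_convention(self):
        m = nb.metrics(nb.ConfusionCounts(tp=0, tn=3, fp=0, fn=0))
        assert m.mcc == 0.0
        assert "MCC_zero_denominator" in m.flags
        assert "SN_undefined" in m.flags
        assert np.isnan(m.sn)

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_acc_identity_and_mcc_range(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        m = nb.metrics(nb.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert m.acc == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert -1.0 <= m.mcc <= 1.0

    def test_mcc_one_iff_no_errors_with_both_classes(self):
        assert nb.metrics(nb.ConfusionCounts(tp=3, tn=4, fp=0, fn=0)).mcc == 1.0
        for c in [nb.ConfusionCounts(tp=3, tn=4, fp=1, fn=0),
                  nb.ConfusionCounts(tp=3, tn=4, fp=0, fn=1)]:
            assert nb.metrics(c).mcc < 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert nb.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert nb.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            nb.roc_auc([1, 1], [0.2, 0.8])

    def test_matches_rank_statistic_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            # coarse grid forces tied scores
            s = rng.integers(0, 10, n) / 10.0
            assert nb.roc_auc(y, s) == pytest.approx(
                rank_statistic_auc(y, s), abs=1e-12)

    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        s = rng.integers(0, 20, 300) / 20.0
        assert nb.roc_auc(y, s) + nb.roc_auc(y, -s) == pytest.approx(1.0,
                                                                     abs=1e-12)

    def test_curve_is_anchored_and_monotone(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        fpr, tpr, _ = nb.roc_curve(y, s)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


def _fast_config():
    return nb.ModelConfig(embedding_dim=4, conv_filters=4, lstm_units=4,
                          dense_units=4, epochs=0, validation_fraction=0.0,
                          seed=0)


class TestKFold:
    def test_folds_disjoint_exhaustive_stratified(self):
        ds = nb.generate(nb.SyntheticConfig(n_pos=25, n_neg=25, seed=0))
        folds = stratified_fold_indices(ds.labels, k=5, seed=0)
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(50))
        global_ratio = ds.labels.mean()
        for _, test in folds:
            assert test.size == 10
            # per-fold class ratio within one sample of the global ratio
            assert abs(ds.labels[test].sum() - global_ratio * test.size) <= 1

    def test_same_seed_reproduces_folds(self):
        labels = np.r_[np.ones(30, dtype=int), np.zeros(30, dtype=int)]
        a = stratified_fold_indices(labels, 5, seed=11)
        b = stratified_fold_indices(labels, 5, seed=11)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_leave_one_out_with_relaxed_stratification(self):
        ds = nb.generate(nb.SyntheticConfig(n_pos=4, n_neg=4, seed=0))
        folds = stratified_fold_indices(ds.labels, k=8, seed=0,
                                        stratified=False)
        assert all(test.size == 1 for _, test in folds)

    def test_class_too_small_raises(self):
        labels = np.r_[np.ones(3, dtype=int), np.zeros(30, dtype=int)]
        with pytest.raises(TrainingError):
            stratified_fold_indices(labels, 5, seed=0)

    def test_protocol_runs_and_pools_every_sample(self):
        ds = nb.generate(nb.SyntheticConfig(n_pos=15, n_neg=15, seed=0))
        result = nb.kfold_cv(ds, _fast_config(), k=5, seed=0)
        assert len(result.per_split) == 5
        assert result.pooled_scores.shape == (30,)
        assert np.isfinite(result.pooled_auc())
        summary = result.summary()
        frame = result.to_frame()
        assert summary.loc["ACC", "mean"] == pytest.approx(frame["ACC"].mean())
        assert summary.loc["ACC", "sd"] == pytest.approx(
            frame["ACC"].std(ddof=1))


class TestRepeatedHoldout:
    def test_split_sizes_and_determinism(self):
        ds = nb.generate(nb.SyntheticConfig(n_pos=100, n_neg=1000, seed=0))
        result = nb.repeated_holdout(ds, _fast_config(), test_fraction=0.1,
                                     repeats=3, seed=0)
        assert [d["test_size"] for d in result.split_descriptors] == [110] * 3
        again = nb.repeated_holdout(ds, _fast_config(), test_fraction=0.1,
                                    repeats=3, seed=0)
        np.testing.assert_array_equal(result.pooled_scores,
                                      again.pooled_scores)

    def test_single_repeat_reports_nan_free_mean(self):
        ds = nb.generate(nb.SyntheticConfig(n_pos=30, n_neg=30, seed=1))
        result = nb.repeated_holdout(ds, _fast_config(), test_fraction=0.2,
                                     repeats=1, seed=0)
        assert len(result.per_split) == 1

    def test_bad_fraction_rejected(self):
        ds = nb.generate(nb.SyntheticConfig(n_pos=10, n_neg=10, seed=0))
        with pytest.raises(ValueError):
            nb.repeated_holdout(ds, _fast_config(), test_fraction=1.5)


class TestWelch:
    def test_identical_vectors_give_p_one(self):
        a = [0.9, 0.91, 0.92, 0.9, 0.91]
        assert nb.compare_ttest(a, a) == pytest.approx(1.0)

    def test_clearly_different_groups(self):
        p = nb.compare_ttest([0.9, 0.91, 0.92, 0.9, 0.91],
                             [0.5, 0.51, 0.5, 0.52, 0.5])
        assert p < 0.001
        # closed-form Welch oracle
        a = np.array([0.9, 0.91, 0.92, 0.9, 0.91])
        b = np.array([0.5, 0.51, 0.5, 0.52, 0.5])
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        t = (a.mean() - b.mean()) / se
        df = (a.var(ddof=1) / 5 + b.var(ddof=1) / 5) ** 2 / (
            (a.var(ddof=1) / 5) ** 2 / 4 + (b.var(ddof=1) / 5) ** 2 / 4)
        expected = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_symmetry_in_argument_order(self):
        a, b = [0.8, 0.82, 0.81], [0.7, 0.75, 0.72]
        assert nb.compare_ttest(a, b) == pytest.approx(nb.compare_ttest(b, a))

    def test_constant_equal_groups(self):
        assert nb.compare_ttest([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            nb.compare_ttest([0.5], [0.4, 0.6])
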