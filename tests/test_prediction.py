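"""Classifier evaluation: LOOCV, ROC/AUC, Youden, DeLong, grid search."""

import numpy as np
import pytest

from nwuct import (
    ConfusionMatrix,
    ModelConfig,
    confusion_metrics,
    delong_test,
    loocv_evaluate,
    reconstruct_confusion,
    rf_grid_search,
    roc_auc,
    round_half_up,
    time_normalized_nwu,
    youden_cutoff,
)


def pairwise_auc(scores, labels):
    """All-pairs Mann-Whitney probability with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestConfusionMetrics:
    def test_study_rf_row_from_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=33, fn=6, tn=73, fp=4))
        assert round_half_up(m["acc"]) == 0.91
        assert round_half_up(m["sen"]) == 0.85
        assert round_half_up(m["spe"]) == 0.95
        assert round_half_up(m["ppv"]) == 0.89
        assert round_half_up(m["npv"]) == 0.92
        assert m["mcc"] == pytest.approx(0.805, abs=5e-4)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fn=0, tn=20, fp=0))
        for key in ("acc", "sen", "spe", "ppv", "npv", "f1", "mcc"):
            assert m[key] == pytest.approx(1.0)

    def test_univariate_cutoff_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tp=25, fn=14, tn=70, fp=7))
        assert round_half_up(m["mcc"]) == 0.58

    def test_mcc_zero_denominator_flagged(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, tn=10, fp=5))
        assert m["mcc"] == 0.0 and m["degenerate_mcc"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, tn=1, fp=0)

    def test_mcc_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            m = confusion_metrics(ConfusionMatrix(int(tp), int(fp), int(tn), int(fn)))
            assert -1.0 <= m["mcc"] <= 1.0


class TestReconstructConfusion:
    def test_printed_sen_spe_identify_unique_matrix(self):
        cm = reconstruct_confusion(0.64, 0.91, n_pos=39, n_neg=77)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (25, 14, 70, 7)

    def test_ambiguous_printed_values_rejected(self):
        # SEN 0.5 with 100 positives: tp 50 only; but 0.5 with 2 positives -> tp=1 ok;
        # an inconsistent value has zero candidates
        with pytest.raises(ValueError):
            reconstruct_confusion(0.33, 0.91, n_pos=2, n_neg=77)


class TestRocAuc:
    def test_all_tied_scores_give_half(self):
        labels = [0, 1] * 10
        _, auc = roc_auc(np.ones(20), labels)
        assert auc == pytest.approx(0.5)

    def test_perfectly_ordered_scores(self):
        scores = np.arange(10, dtype=float)
        labels = (scores >= 5).astype(int)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_matches_all_pairs_counting(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=30).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(scores * 2), labels)
        assert a1 == pytest.approx(a2)


class TestYoudenCutoff:
    def test_separable_scores_classify_all_correctly(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        roc, _ = roc_auc(scores, labels)
        t = youden_cutoff(roc)
        preds = scores >= t
        assert np.array_equal(preds, labels.astype(bool))

    def test_single_top_positive(self):
        scores = np.array([0.1, 0.2, 0.3, 0.9])
        labels = np.array([0, 0, 0, 1])
        roc, _ = roc_auc(scores, labels)
        t = youden_cutoff(roc)
        assert 0.3 < t <= 0.9

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=40).round(1)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        roc, _ = roc_auc(scores, labels)
        t = youden_cutoff(roc)

        def j_at(threshold):
            preds = scores >= threshold
            tpr = (preds & (labels == 1)).sum() / (labels == 1).sum()
            fpr = (preds & (labels == 0)).sum() / (labels == 0).sum()
            return tpr - fpr

        best_j = max(j_at(c) for c in np.unique(scores))
        assert j_at(t) == pytest.approx(best_j)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        auc_a, auc_b, z, p = delong_test(scores, scores.copy(), labels)
        assert auc_a == auc_b
        assert p == 1.0

    def test_monotone_transform_has_zero_auc_difference(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        auc_a, auc_b, _, p = delong_test(scores, np.tanh(scores), labels)
        assert auc_a == pytest.approx(auc_b)
        assert p == 1.0

    def test_agrees_with_paired_bootstrap(self):
        rng = np.random.default_rng(17)
        n = 50
        labels = np.array([1] * 20 + [0] * 30)
        signal = labels * 1.2
        scores_a = signal + rng.normal(size=n)
        scores_b = 0.6 * signal + rng.normal(size=n)
        _, _, _, p_delong = delong_test(scores_a, scores_b, labels)

        reps = 10_000
        diffs = np.empty(reps)
        kept = 0
        while kept < reps:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() == lab.max():
                continue
            diffs[kept] = (pairwise_auc_fast(scores_a[idx], lab)
                           - pairwise_auc_fast(scores_b[idx], lab))
            kept += 1
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        p_boot = min(1.0, p_boot)
        assert abs(p_delong - p_boot) < 0.03

    def test_type_one_error_near_nominal(self):
        # two independent noise scores with equal (chance) AUC: the test
        # should reject at roughly the nominal 5% level
        rng = np.random.default_rng(18)
        rejections = 0
        n_sims = 1000
        labels = np.array([1] * 25 + [0] * 35)
        for _ in range(n_sims):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            _, _, _, p = delong_test(a, b, labels)
            rejections += p < 0.05
        assert abs(rejections / n_sims - 0.05) < 0.02


def pairwise_auc_fast(scores, labels):
    from scipy.stats import rankdata

    pos = labels == 1
    r = rankdata(scores)
    m = pos.sum()
    n = labels.size - m
    return (r[pos].sum() - m * (m + 1) / 2) / (m * n)


class TestLOOCV:
    def test_separable_feature_gives_perfect_metrics(self):
        X = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        for clf in ("svm", "lr", "rf"):
            report = loocv_evaluate(X, y, ModelConfig(classifier=clf))
            assert report.metrics["acc"] == 1.0
            assert report.auc == 1.0

    def test_fold_count_and_label_alignment(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(15, 3))
        y = rng.integers(0, 2, size=15)
        y[:2] = [0, 1]
        report = loocv_evaluate(X, y, ModelConfig(classifier="lr"))
        assert report.scores.shape == (15,)
        assert report.confusion.n == 15

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            loocv_evaluate(X, np.ones(5, int), ModelConfig(classifier="lr"))

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(20, 4))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        c = ModelConfig(classifier="rf", rf_random_state=10, rf_n_estimators=100)
        r1 = loocv_evaluate(X, y, c)
        r2 = loocv_evaluate(X, y, c)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_shuffled_labels_show_no_optimistic_bias(self):
        # Permutation null: with labels shuffled the pooled LOOCV AUC must
        # not rise above chance.  Pooled LOOCV scores are in fact known to be
        # *pessimistically* biased under the null (each held-out subject's
        # training prior is anti-correlated with its label), so the mean sits
        # below 0.5 at this sample size; the test pins both sides.
        rng = np.random.default_rng(21)
        X = rng.normal(size=(60, 2))
        aucs = []
        for _ in range(100):
            y = np.zeros(60, int)
            y[rng.choice(60, size=25, replace=False)] = 1
            report = loocv_evaluate(X, y, ModelConfig(classifier="lr"))
            aucs.append(report.auc)
        assert 0.30 < np.mean(aucs) < 0.55


class TestRFGridSearch:
    def test_grid_of_size_one_returns_that_combination(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(12, 3))
        y = np.array([0, 1] * 6)
        config = ModelConfig(classifier="rf", rf_random_state_grid=(5,),
                             rf_n_estimators_grid=(50,))
        best, table = rf_grid_search(X, y, config)
        assert best == (5, 50)
        assert len(table) == 1

    def test_default_grids_have_80_cells_and_best_maximises_table(self):
        rng = np.random.default_rng(23)
        X = np.concatenate([rng.normal(0, 1, (6, 2)), rng.normal(2, 1, (6, 2))])
        y = np.array([0] * 6 + [1] * 6)
        config = ModelConfig(
            classifier="rf",
            rf_n_estimators_grid=tuple(range(100, 1001, 100))[:3],
            rf_random_state_grid=tuple(range(2, 17, 2))[:2],
        )
        best, table = rf_grid_search(X, y, config)
        assert len(table) == 6
        best_auc = max(r["auc"] for r in table)
        assert any(r["random_state"] == best[0] and r["n_estimators"] == best[1]
                   and r["auc"] == best_auc for r in table)
        # the full study grids enumerate 8 x 10 combinations
        assert len(ModelConfig().rf_random_state_grid) == 8
        assert len(ModelConfig().rf_n_estimators_grid) == 10


class TestTimeNormalisedNWU:
    def test_log_variant_identity_at_t_e_minus_1(self):
        _, per_log = time_normalized_nwu(0.2, np.e - 1)
        assert per_log == pytest.approx(0.2)

    def test_linear_variant_identity_at_t_1(self):
        per_t, _ = time_normalized_nwu(0.2, 1.0)
        assert per_t == pytest.approx(0.2)

    def test_doubling_time_halves_linear_variant(self):
        a, _ = time_normalized_nwu(0.2, 3.0)
        b, _ = time_normalized_nwu(0.2, 6.0)
        assert b == pytest.approx(a / 2)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            time_normalized_nwu(0.2, 0.0)
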