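"""Metrics and the statistical validation protocol."""

import numpy as np
import pytest

from oracles import trapezoid_auc

from gradiomics.errors import ConfigurationError, DataError
from gradiomics.stats import (
    holm_bonferroni,
    mcnemar,
    metrics,
    metrics_from_counts,
    paired_t,
    permutation_test,
    wilcoxon_signed_rank,
)


class TestMetrics:
    def test_reported_confusion_counts(self):
        """227/11/217/2: sensitivity 95.4%, specificity 99.1%, accuracy 97.16%."""
        m = metrics_from_counts(tp=227, fn=11, tn=217, fp=2)
        assert m.sensitivity == pytest.approx(227 / 238)
        assert round(m.sensitivity * 100, 1) == 95.4
        assert round(m.specificity * 100, 1) == 99.1
        assert round(m.accuracy * 100, 2) == 97.16
        assert round(m.missed_lesion_rate * 100, 1) == 4.6
        assert round(m.mislabeled_healthy_rate * 100, 1) == 0.9

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        m = metrics(y, y, y.astype(float))
        for name in ("accuracy", "precision", "recall", "specificity", "f1", "auc"):
            assert getattr(m, name) == 1.0

    def test_constant_probabilities_give_auc_half(self):
        y = np.array([0, 1, 0, 1])
        m = metrics(y, y, np.full(4, 0.7))
        assert m.auc == 0.5  # all ties counted half

    def test_auc_equals_trapezoidal_integration(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, size=50)
            if len(np.unique(y)) < 2:
                continue
            prob = np.round(rng.random(50), 2)  # force ties
            m = metrics(y, (prob >= 0.5).astype(int), prob)
            assert m.auc == pytest.approx(trapezoid_auc(y, prob), abs=1e-12)

    def test_zero_denominators_reported_as_nan_with_flag(self):
        m = metrics_from_counts(tp=0, fn=0, tn=5, fp=0)
        assert np.isnan(m.recall)
        assert "recall" in m.undefined
        assert np.isnan(m.precision)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            metrics([0, 1], [0])


class TestPairedT:
    def test_identical_scores_degenerate(self):
        r = paired_t([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert r.degenerate and r.p_value == 1.0

    def test_consistent_small_differences_significant(self):
        a = np.array([0.91, 0.92, 0.93, 0.90, 0.915])
        b = a - 0.01 + np.array([1, -1, 1, -1, 1]) * 1e-4
        r = paired_t(a, b)
        assert abs(r.statistic) > 10
        assert r.p_value < 0.01

    def test_textbook_five_pairs_hand_computed(self):
        a, b = [10.0, 12.0, 9.0, 11.0, 13.0], [8.0, 9.0, 9.0, 10.0, 11.0]
        d = np.subtract(a, b)  # [2, 3, 0, 1, 2]
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        from scipy import stats as sps

        p_hand = 2 * sps.t.sf(abs(t_hand), df=4)
        r = paired_t(a, b)
        assert r.statistic == pytest.approx(t_hand)
        assert r.p_value == pytest.approx(p_hand)


class TestWilcoxon:
    def test_five_same_sign_exact(self):
        r = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert r.p_value == pytest.approx(2 / 32)  # 0.0625

    def test_four_same_sign_exact(self):
        r = wilcoxon_signed_rank([1, 2, 3, 4], [0, 1, 2, 3])
        assert r.p_value == pytest.approx(2 / 16)  # 0.125

    def test_balanced_pair_p_one(self):
        assert wilcoxon_signed_rank([1.0, 0.0], [0.0, 1.0]).p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.degenerate and r.p_value == 1.0

    def test_matches_scipy_exact_when_tie_free(self, rng):
        from scipy import stats as sps

        for _ in range(5):
            a, b = rng.normal(size=9), rng.normal(size=9)
            mine = wilcoxon_signed_rank(a, b).p_value
            ref = sps.wilcoxon(a - b, zero_method="wilcox", method="exact").pvalue
            assert mine == pytest.approx(ref)


class TestPermutation:
    def test_constant_score_p_one(self):
        r = permutation_test(lambda y: 0.5, np.repeat([0, 1], 10),
                             np.tile([0, 1], 10), n_perm=19, seed=0)
        assert r.p_value == 1.0

    def test_strong_signal_p_zero_with_20_permutations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = (x > 0).astype(int)
        folds = np.arange(100) % 5

        def score(labels):
            return abs(np.corrcoef(x, labels)[0, 1])

        r = permutation_test(score, y, folds, n_perm=20, seed=3)
        assert r.p_value == 0.0
        assert len(r.null_scores) == 20

    def test_shuffles_respect_folds(self):
        y = np.repeat([0, 1], 10)
        folds = np.repeat([0, 1], 10)  # fold 0 all-zeros, fold 1 all-ones

        def score(labels):
            # within-fold shuffles cannot change per-fold sums
            assert labels[:10].sum() == 0 and labels[10:].sum() == 10
            return 0.0

        permutation_test(score, y, folds, n_perm=5, seed=1)

    def test_plus_one_variant(self):
        r = permutation_test(lambda y: float(np.sum(y)), np.repeat([0, 1], 5),
                             np.zeros(10), n_perm=9, seed=0, plus_one=True)
        assert r.p_value == pytest.approx(1.0)  # permutation-invariant statistic

    def test_invalid_n_perm(self):
        with pytest.raises(ConfigurationError):
            permutation_test(lambda y: 0.0, [0, 1], [0, 0], n_perm=0)


class TestMcnemar:
    def test_equal_discordance_p_one(self):
        y = np.repeat([0, 1], 10)
        a = y.copy(); a[:3] = 1 - a[:3]
        b = y.copy(); b[-3:] = 1 - b[-3:]
        assert mcnemar(a, b, y).p_value == pytest.approx(1.0)

    def test_one_sided_discordance_binomial_tail(self):
        y = np.ones(10, int)
        a, b = np.zeros(10, int), np.ones(10, int)  # b right 10 times, a never
        r = mcnemar(a, b, y)
        assert r.p_value == pytest.approx(2 * 0.5**10)  # ~0.00195

    def test_two_eight_split_exact(self):
        y = np.ones(20, int)
        a = np.ones(20, int); a[:8] = 0   # a wrong on 8
        b = np.ones(20, int); b[8:10] = 0  # b wrong on 2 (disjoint)
        r = mcnemar(a, b, y)
        assert r.p_value == pytest.approx(0.109375)  # 2 * binom.cdf(2, 10, 0.5)

    def test_large_counts_use_corrected_chi_square(self, rng):
        y = rng.integers(0, 2, 500)
        a = np.where(rng.random(500) < 0.9, y, 1 - y)
        b = np.where(rng.random(500) < 0.8, y, 1 - y)
        r = mcnemar(a, b, y)
        assert 0.0 <= r.p_value <= 1.0


class TestHolmBonferroni:
    def test_hand_computed_step_down(self):
        reject, adjusted = holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
        assert reject.tolist() == [True, False, False]
        assert adjusted == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones_no_rejections(self):
        reject, adjusted = holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.all(adjusted == 1.0)

    def test_single_p_plain_comparison(self):
        reject, adjusted = holm_bonferroni([0.04], alpha=0.05)
        assert reject.tolist() == [True]
        assert adjusted == pytest.approx([0.04])

    def test_holm_no_less_powerful_than_bonferroni(self, rng):
        for _ in range(20):
            p = rng.random(6)
            holm_reject, _ = holm_bonferroni(p, alpha=0.05)
            bonf_reject = p <= 0.05 / len(p)
            assert np.all(holm_reject[bonf_reject])

    def test_invalid_p_values(self):
        with pytest.raises(ConfigurationError):
            holm_bonferroni([0.5, 1.2])
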