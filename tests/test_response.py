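import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dwiadc import (
    POOR_RESPONSE,
    RESPONSE,
    ConfusionMatrix,
    bonferroni,
    clopper_pearson,
    kruskal_wallis,
    mann_whitney,
    metrics_from_confusion,
    reconstruct_confusion,
    roc_analysis,
    youden_cut_point,
)


def _labels(n_pos, n_neg):
    return np.array([RESPONSE] * n_pos + [POOR_RESPONSE] * n_neg)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_exact_small_sample(self):
        # fully separated groups of 3: U = 0
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        # oracle: enumerate all C(6,3) = 20 rank assignments
        ranks = range(1, 7)
        u_obs = 0
        count_extreme = 0
        for combo in itertools.combinations(ranks, 3):
            u = sum(combo) - 3 * 4 / 2
            u = min(u, 9 - u)  # two-sided: either tail
            if u <= u_obs:
                count_extreme += 1
        assert r.p_value == pytest.approx(count_extreme / 20)
        assert r.p_value == pytest.approx(0.1)

    def test_large_shifted_normals(self, rng):
        a = rng.normal(1.0, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        assert mann_whitney(a, b).p_value < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_group_summaries(self):
        r = mann_whitney([1, 2, 9], [5])
        assert r.group_summaries["a"] == {
            "median": 2.0, "min": 1.0, "max": 9.0, "n": 3
        }


class TestKruskalWallis:
    def test_two_groups_matches_mann_whitney(self, rng):
        """For k = 2 the (tie-corrected, no-continuity) normal-approximation
        Mann-Whitney p equals the Kruskal-Wallis chi-square p."""
        for _ in range(5):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0.5, 1, 15)
            p_kw = kruskal_wallis([a, b]).p_value
            p_mw = mann_whitney(a, b).p_value
            assert p_kw == pytest.approx(p_mw, abs=1e-6)

    def test_all_equal_h_zero(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_three_separated_groups(self, rng):
        groups = [rng.normal(m, 0.5, 15) for m in (0.0, 2.0, 4.0)]
        assert kruskal_wallis(groups).p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestBonferroni:
    def test_basic_and_capping(self):
        np.testing.assert_allclose(bonferroni([0.01], 8), [0.08])
        np.testing.assert_allclose(bonferroni([0.5], 8), [1.0])
        np.testing.assert_allclose(bonferroni([0.001, 0.02], 2), [0.002, 0.04])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 8)

    def test_family_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.array([10, 11, 12, 1, 2, 3], dtype=float)
        roc = roc_analysis(scores, _labels(3, 3))
        assert roc.auc == pytest.approx(1.0)
        assert roc.significant

    def test_chance_level_under_permutation(self, rng):
        scores = rng.normal(size=1000)
        labels = _labels(500, 500)
        rng.shuffle(labels)
        roc = roc_analysis(scores, labels)
        assert abs(roc.auc - 0.5) < 0.05

    def test_auc_equals_u_statistic_fuzz(self, rng):
        """Algebraic identity AUC = U / (n+ * n-), including under heavy
        ties."""
        for _ in range(50):
            n_pos = int(rng.integers(2, 30))
            n_neg = int(rng.integers(2, 30))
            if rng.random() < 0.5:
                scores = rng.normal(size=n_pos + n_neg)
            else:
                scores = rng.integers(0, 4, size=n_pos + n_neg).astype(float)
            roc = roc_analysis(scores, _labels(n_pos, n_neg))
            u = stats.mannwhitneyu(
                scores[:n_pos], scores[n_pos:], alternative="two-sided"
            ).statistic
            assert roc.auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_sklearn_auc_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80) + np.r_[np.full(40, 0.8), np.zeros(40)]
        roc = roc_analysis(scores, _labels(40, 40))
        assert roc.auc == pytest.approx(
            roc_auc_score([1] * 40 + [0] * 40, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], np.array([RESPONSE, RESPONSE]))

    def test_significance_rule_requires_both_conditions(self, rng):
        # small sample: AUC can exceed 0.6 without significance
        scores = np.array([3.0, 1.0, 2.0, 0.5])
        roc = roc_analysis(scores, _labels(2, 2))
        assert roc.auc > 0.6
        assert roc.p_value >= 0.05
        assert not roc.significant


class TestYoudenCutPoint:
    def test_perfect_separation_tie_break(self):
        scores = np.array([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        m = youden_cut_point(roc_analysis(scores, _labels(3, 3)))
        assert m.youden_j == pytest.approx(1.0)
        # smallest qualifying distinct score: the largest negative score
        assert m.cut_point == 3.0
        assert m.sensitivity == 100.0 and m.specificity == 100.0

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            n_pos = int(rng.integers(3, 25))
            n_neg = int(rng.integers(3, 25))
            scores = np.round(rng.normal(size=n_pos + n_neg), 1)
            labels = _labels(n_pos, n_neg)
            m = youden_cut_point(roc_analysis(scores, labels))
            # exhaustive oracle over every distinct threshold
            best_j, best_c = -2.0, None
            for c in sorted(set(scores)):
                sens = float((scores[:n_pos] > c).sum()) / n_pos
                spec = 1 - float((scores[n_pos:] > c).sum()) / n_neg
                j = sens + spec - 1
                if j > best_j:
                    best_j, best_c = j, c
            assert m.youden_j == pytest.approx(best_j, abs=1e-12)
            assert m.cut_point == pytest.approx(best_c)

    def test_identical_distributions_j_near_zero(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        m = youden_cut_point(roc_analysis(scores, _labels(3, 3)))
        assert abs(m.youden_j) < 1e-12

    def test_confusion_counts_partition_cohort(self, rng):
        scores = rng.normal(size=30)
        m = youden_cut_point(roc_analysis(scores, _labels(18, 12)))
        cm = m.confusion
        assert cm.tp + cm.fn == 18
        assert cm.tn + cm.fp == 12


class TestReconstructConfusion:
    def test_published_row_pct_delta_p75(self):
        """73.7/90.0 sensitivity/specificity on a 38/10 cohort gives
        PPV 96.6 and NPV 47.4."""
        cm = reconstruct_confusion(73.7, 90.0, 38, 10)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (28, 10, 9, 1)
        assert cm.ppv() == pytest.approx(96.6, abs=0.05)
        assert cm.npv() == pytest.approx(47.4, abs=0.05)

    def test_published_row_delta_p75(self):
        cm = reconstruct_confusion(79.0, 90.0, 38, 10)
        assert (cm.tp, cm.fp) == (30, 1)
        assert cm.ppv() == pytest.approx(96.8, abs=0.05)
        assert cm.npv() == pytest.approx(52.9, abs=0.05)

    def test_perfect_metrics(self):
        cm = reconstruct_confusion(100.0, 100.0, 7, 3)
        assert cm.ppv() == 100.0 and cm.npv() == 100.0

    def test_ppv_prevalence_identity(self):
        """PPV = sens*pi / (sens*pi + (1-spec)(1-pi)) for every published
        sensitivity/specificity pair on the 38/10 cohort."""
        table3 = [
            (65.8, 90.0), (55.3, 100.0), (86.8, 70.0), (68.4, 90.0),
            (71.1, 80.0), (65.8, 90.0), (84.2, 80.0), (50.0, 100.0),
            (57.9, 90.0), (60.5, 90.0), (81.6, 80.0), (55.3, 90.0),
            (57.9, 100.0), (79.0, 90.0), (60.5, 90.0), (68.4, 80.0),
            (73.7, 90.0),
        ]
        pi = 38 / 48
        for sens, spec in table3:
            cm = reconstruct_confusion(sens, spec, 38, 10)
            s, p = cm.sensitivity() / 100, cm.specificity() / 100
            expected = 100 * s * pi / (s * pi + (1 - p) * (1 - pi))
            assert cm.ppv() == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(110.0, 90.0, 38, 10)


class TestClopperPearson:
    def test_published_ci_9_of_10(self):
        low, high = clopper_pearson(9, 10)
        assert low == pytest.approx(55.5, abs=0.05)
        assert high == pytest.approx(99.7, abs=0.05)

    def test_published_ci_10_of_10(self):
        low, high = clopper_pearson(10, 10)
        assert low == pytest.approx(69.2, abs=0.05)
        assert high == 100.0

    def test_zero_successes_closed_form(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert high == pytest.approx(100 * (1 - 0.025 ** (1 / 10)), rel=1e-10)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            low, high = clopper_pearson(k, n)
            assert low <= 100 * k / n <= high

    def test_coverage_simulation(self, rng):
        """Nominal 95% intervals at n=10, p=0.9 over 1e4 replicates cover
        at >= 95% (exact intervals are conservative)."""
        p = 0.9
        ks = rng.binomial(10, p, size=10_000)
        covered = 0
        ci_cache = {k: clopper_pearson(k, 10) for k in range(11)}
        for k in ks:
            low, high = ci_cache[k]
            covered += low <= 100 * p <= high
        assert covered / 10_000 >= 0.95 - 0.01  # Monte-Carlo slack, one-sided

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestMetricsFromConfusion:
    def test_cis_bracket_points(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=28, fp=1, tn=9, fn=10))
        assert m.sensitivity_ci[0] <= m.sensitivity <= m.sensitivity_ci[1]
        assert m.specificity_ci[0] <= m.specificity <= m.specificity_ci[1]
        assert m.ppv_ci[0] <= m.ppv <= m.ppv_ci[1]
        assert m.npv_ci[0] <= m.npv <= m.npv_ci[1]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=1, fn=1)


def test_mann_whitney_type_i_error_smoke(rng):
    """Null rejection rate at the study's 38 vs 10 split stays near the
    nominal 5% level (smoke version; the full 1e4-replicate check runs in
    the acceptance suite)."""
    rejections = 0
    reps = 1000
    for _ in range(reps):
        a = rng.normal(size=38)
        b = rng.normal(size=10)
        rejections += mann_whitney(a, b).p_value < 0.05
    assert 0.02 < rejections / reps < 0.09
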