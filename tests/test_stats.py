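"""Tests for the evaluation statistics (calibration, discrimination,
agreement, group comparisons)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctoscore.stats import (
    auc_ci,
    auc_mann_whitney,
    chi_square_test,
    cohen_kappa,
    fisher_exact_2x2,
    hosmer_lemeshow,
    kruskal_wallis,
    logistic_recalibration,
    one_way_anova,
    percent,
    roc_points,
    tier_success_table,
)

from conftest import tier_fixture_cohort


def brute_force_auc(scores, outcomes):
    """Oracle: average over all (failure, success) pairs of the ranking
    indicator with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(131, 144, 91.0), (0, 144, 0.0), (26, 37, 70.3), (1, 8, 12.5)],
    )
    def test_examples(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up_rounding(self):
        assert percent(1, 16) == 6.3  # 6.25 rounds up, not to even

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent(1, 0)


class TestTierTable:
    def test_backsolved_fixture_reproduces_tier_percentages(self):
        table = tier_success_table(tier_fixture_cohort())
        assert [r.n for r in table.rows] == [103, 24, 13, 4]
        assert [r.technical_pct for r in table.rows] == [99.0, 87.5, 53.8, 25.0]
        assert table.total_technical == 131
        assert table.total_n == 144

    def test_empty_tier_marked_not_zero(self):
        from conftest import make_tier_record
        from ctoscore.simulate import Cohort

        cohort = Cohort(records=tuple(make_tier_record(f"c{i}", 0, True) for i in range(5)))
        table = tier_success_table(cohort)
        assert table.rows[0].technical_pct == 100.0
        assert table.rows[1].n == 0 and table.rows[1].technical_pct is None


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 4, 5], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc_mann_whitney([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_pairwise_example(self):
        # failures {3,2} vs successes {1,2,3}: (1+1+0.5+1+0.5+0)/6
        auc = auc_mann_whitney([3, 2, 1, 2, 3], [1, 1, 0, 0, 0])
        assert auc == pytest.approx(4.0 / 6.0, abs=1e-12)

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2], [1, 1])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(4, 25))
        scores = data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n)
        )
        outcomes = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(
            brute_force_auc(scores, outcomes), abs=1e-12
        )

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_negation_symmetry_without_ties(self, data):
        n = data.draw(st.integers(4, 20))
        scores = data.draw(
            st.lists(st.integers(0, 1000), min_size=n, max_size=n, unique=True)
        )
        outcomes = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        a = auc_mann_whitney(scores, outcomes)
        b = auc_mann_whitney([-s for s in scores], outcomes)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_trapezoid_equivalence_on_roc_points(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 7, size=200)
        outcomes = (rng.random(200) < 0.3).astype(int)
        _, sens, spec = roc_points(scores, outcomes)
        area = float(np.trapezoid(sens, 1 - spec))
        assert area == pytest.approx(auc_mann_whitney(scores, outcomes), abs=1e-12)


class TestAucCi:
    def test_interval_contains_point_estimate(self, rng):
        scores = rng.integers(0, 7, size=300)
        outcomes = (rng.random(300) < 0.2).astype(int)
        auc = auc_mann_whitney(scores, outcomes)
        lo, hi = auc_ci(scores, outcomes)
        assert lo <= auc <= hi

    def test_truncation_at_one_for_perfect_separation(self):
        scores = [1, 1, 2, 2, 5, 5, 6, 6]
        outcomes = [0, 0, 0, 0, 1, 1, 1, 1]
        lo, hi = auc_ci(scores, outcomes)
        assert hi == 1.0

    def test_bootstrap_close_to_delong(self, rng):
        scores = rng.normal(size=400) + np.repeat([0.0, 1.0], 200)
        outcomes = np.repeat([0, 1], 200)
        d = auc_ci(scores, outcomes, method="delong")
        b = auc_ci(scores, outcomes, method="bootstrap", n_boot=500, seed=4)
        assert d[0] == pytest.approx(b[0], abs=0.05)
        assert d[1] == pytest.approx(b[1], abs=0.05)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            auc_ci([1, 2, 3], [0, 0, 1])


class TestLogisticRecalibration:
    def test_independent_outcomes_give_flat_fit(self, rng):
        scores = np.tile([0, 1, 2, 3], 500)
        outcomes = rng.permutation(np.repeat([0, 1], 1000))  # independent of score
        fit = logistic_recalibration(scores, outcomes)
        assert fit.converged
        assert fit.slope == pytest.approx(0.0, abs=0.1)
        assert np.allclose(fit.probabilities, 0.5, atol=0.08)

    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm

        scores = rng.integers(0, 7, size=500).astype(float)
        p = 1 / (1 + np.exp(-(-2.0 + 0.6 * scores)))
        outcomes = (rng.random(500) < p).astype(int)
        fit = logistic_recalibration(scores, outcomes)
        ref = sm.Logit(outcomes, sm.add_constant(scores)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_separation_flagged(self):
        fit = logistic_recalibration([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert fit.separated
        assert not fit.converged


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero_statistic(self):
        # two probability levels, observed counts exactly matching expected
        p = [0.2] * 10 + [0.8] * 10
        y = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0] + [1] * 8 + [0, 0]
        hl = hosmer_lemeshow(p, y, n_groups=10)
        assert hl.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_group_worked_example(self):
        p = [0.2] * 50 + [0.8] * 50
        y = [1] * 15 + [0] * 35 + [1] * 35 + [0] * 15
        hl = hosmer_lemeshow(p, y, n_groups=10)
        assert hl.statistic == pytest.approx(6.25)
        assert hl.df == 0
        assert hl.df_degenerate
        assert np.isnan(hl.p_value)

    def test_group_with_zero_expected_named(self):
        p = [0.0] * 30 + [0.5] * 30 + [0.9] * 30
        y = [0] * 30 + [1] * 15 + [0] * 15 + [1] * 27 + [0] * 3
        with pytest.raises(ValueError, match="group"):
            hosmer_lemeshow(p, y, n_groups=3)

    def test_invariant_under_monotone_grouping_transform(self, rng):
        p = rng.uniform(0.05, 0.95, size=400)
        y = (rng.random(400) < p).astype(int)
        base = hosmer_lemeshow(p, y)
        transformed = hosmer_lemeshow(p, y, group_values=np.log(p / (1 - p)))
        assert transformed.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert transformed.df == base.df

    def test_minimum_groups(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5, 0.5], [0, 1], n_groups=2)


class TestCohenKappa:
    def test_identical_sequences(self):
        res = cohen_kappa(list("abcabc"), list("abcabc"))
        assert res.kappa == 1.0
        assert res.observed_agreement == 1.0

    def test_disjoint_constant_raters(self):
        res = cohen_kappa(["x"] * 10, ["y"] * 10)
        assert res.kappa == 0.0
        assert res.observed_agreement == 0.0
        assert res.expected_agreement == 0.0

    def test_hand_worked_2x2_table(self):
        # agreement table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5
        a = ["p"] * 25 + ["n"] * 25
        b = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
        res = cohen_kappa(a, b)
        assert res.kappa == pytest.approx(0.4, abs=1e-12)
        assert res.observed_agreement == pytest.approx(0.7)
        assert res.expected_agreement == pytest.approx(0.5)

    def test_degenerate_identical_constant(self):
        res = cohen_kappa(["x"] * 5, ["x"] * 5)
        assert res.kappa == 1.0
        assert res.degenerate

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 4, size=200)
        b = rng.integers(0, 4, size=200)
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_kappa_never_exceeds_observed_agreement(self, data):
        n = data.draw(st.integers(2, 30))
        a = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        b = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        res = cohen_kappa(a, b)
        assert res.kappa <= res.observed_agreement + 1e-12


class TestChiSquare:
    def test_uniform_table_zero_statistic(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1

    def test_4x2_degrees_of_freedom(self):
        stat, df, p = chi_square_test(np.ones((4, 2)) * 5)
        assert df == 3

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_2x2_closed_form(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _, _ = chi_square_test([[a, b], [c, d]])
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_uniform_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_agrees_with_chi_square_on_large_balanced_tables(self):
        table = [[120, 80], [95, 105]]
        _, _, p_chi = chi_square_test(table)
        p_fisher = fisher_exact_2x2(table)
        assert abs(p_chi - p_fisher) < 0.02


class TestAnova:
    def test_equal_groups_zero_f(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)
        assert (df1, df2) == (2, 6)

    def test_two_group_f_equals_t_squared(self, rng):
        from scipy import stats as sps

        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        f, _, _, p = one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(p_t, rel=1e-10)

    def test_matches_scipy_on_three_groups(self, rng):
        from scipy import stats as sps

        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.3, 0.8)]
        f, _, _, p = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_zero_within_variance(self):
        f, _, _, p = one_way_anova([[2, 2], [2, 2]])
        assert f == 0.0 and p == 1.0
        f, _, _, p = one_way_anova([[1, 1], [2, 2]])
        assert np.isinf(f) and p == 0.0


class TestKruskalWallis:
    def test_all_identical(self):
        h, df, p = kruskal_wallis([[3, 3], [3, 3, 3]])
        assert h == 0.0 and p == 1.0

    def test_hand_ranked_toy(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857142857, abs=1e-6)
        assert df == 1

    def test_two_group_direction_consistent_with_mannwhitney(self, rng):
        from scipy import stats as sps

        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 40)
        _, _, p_kw = kruskal_wallis([a, b])
        p_mw = sps.mannwhitneyu(a, b).pvalue
        assert (p_kw < 0.05) == (p_mw < 0.05)
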