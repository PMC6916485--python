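"""Screening statistics against hand computations and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scar16.screening import (
    DegenerateDataError,
    anova_tukey,
    bh_adjust,
    fisher_exact,
    results_table,
    screen,
    simple_regression,
    two_group_t,
)
from scar16.screening import test_distribution as distribution_test


class TestDistribution:
    @pytest.mark.parametrize(
        "counts,expected_p",
        [((11, 13), 0.6829), ((4, 20), 0.0006), ((18, 6), 0.0122), ((17, 7), 0.0382)],
    )
    def test_binary_lr_chi2_matches_published_values(self, counts, expected_p):
        values = ["Y"] * counts[0] + ["N"] * counts[1]
        res = distribution_test(values, "categorical")
        assert res.p == pytest.approx(expected_p, abs=5e-5)

    def test_uniform_split_is_exact_null(self):
        res = distribution_test(["a"] * 12 + ["b"] * 12, "categorical")
        assert res.statistic == 0.0 and res.p == 1.0

    def test_lr_chi2_matches_scipy_power_divergence(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 30, size=rng.integers(2, 6))
            values = [f"l{i}" for i, c in enumerate(counts) for _ in range(c)]
            res = distribution_test(values, "categorical")
            g, p = stats.power_divergence(counts, lambda_="log-likelihood")
            assert res.statistic == pytest.approx(float(g), rel=1e-10)
            assert res.p == pytest.approx(float(p), rel=1e-10)

    def test_continuous_uses_shapiro_wilk(self, rng):
        x = rng.normal(size=30)
        res = distribution_test(x, "continuous")
        w, p = stats.shapiro(x)
        assert res.statistic == pytest.approx(float(w))
        assert res.p == pytest.approx(float(p))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateDataError):
            distribution_test([3.0] * 10, "continuous")
        with pytest.raises(DegenerateDataError):
            distribution_test(["a"] * 10, "categorical")


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == 1.0

    def test_brute_force_hypergeometric_oracle(self):
        # independent enumeration over all tables with the margins of [[8,2],[1,9]]
        table = np.array([[8, 2], [1, 9]])
        n, r1, c1 = 20, 10, 9
        p_obs = stats.hypergeom.pmf(8, n, r1, c1)
        expected = sum(
            stats.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if stats.hypergeom.pmf(a, n, r1, c1) <= p_obs * (1 + 1e-7)
        )
        assert fisher_exact(table).p == pytest.approx(expected, rel=1e-10)
        # frozen cross-check computed with R stats::fisher.test
        assert fisher_exact(table).p == pytest.approx(0.005477494642, abs=1e-9)

    def test_scipy_oracle_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact(t).p == pytest.approx(
                stats.fisher_exact(t)[1], abs=1e-10
            )

    def test_2x3_matches_r_fisher_test(self):
        # frozen value from R stats::fisher.test (network algorithm)
        res = fisher_exact([[8, 2, 1], [1, 9, 5]])
        assert res.p == pytest.approx(0.002712472949, abs=1e-9)

    def test_zero_margin_is_vacuous_not_an_error(self):
        res = fisher_exact([[0, 0], [3, 4]])
        assert res.p == 1.0 and res.warnings

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3, 4], [1, 1, 1, 1]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestGroupComparisons:
    def test_pooled_t_hand_value(self):
        res = two_group_t([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        # pooled sd = 1, se = sqrt(2/3), t = -3/se
        assert res.statistic == pytest.approx(-3 / math.sqrt(2 / 3), rel=1e-9)
        assert res.extra["mean_diff"] == pytest.approx(-3.0)

    def test_identical_groups(self):
        res = two_group_t([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_welch_flag(self, rng):
        y = np.r_[rng.normal(0, 1, 10), rng.normal(0, 5, 10)]
        g = ["a"] * 10 + ["b"] * 10
        res = two_group_t(y, g, welch=True)
        t, p = stats.ttest_ind(y[:10], y[10:], equal_var=False)
        assert res.statistic == pytest.approx(float(t))
        assert res.p == pytest.approx(float(p))

    def test_anova_matches_sum_of_squares_decomposition(self):
        groups = [[0, 0, 1], [5, 5, 6], [9, 10, 11]]
        y = [v for g in groups for v in g]
        labels = [lab for lab, g in zip("abc", groups) for _ in g]
        res = anova_tukey(y, labels)
        grand = np.mean(y)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(sum((v - np.mean(g)) ** 2 for v in g) for g in groups)
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert res.statistic == pytest.approx(f_hand, rel=1e-9)
        assert len(res.posthoc) == 3

    def test_anova_identical_groups(self):
        res = anova_tukey([1, 2, 1, 2, 1, 2], ["a", "a", "b", "b", "c", "c"])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_singleton_levels_excluded_with_warning(self):
        res = anova_tukey([1, 2, 3, 4, 9], ["a", "a", "b", "b", "c"])
        assert res.warnings and "c" in res.warnings[0]
        assert res.n_used == 4


class TestRegression:
    def test_exact_line(self):
        res = simple_regression([2, 4, 6, 8], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(2.0)
        assert res.extra["r2"] == pytest.approx(1.0)

    def test_null_p_values_are_uniform(self, rng):
        # permuted pairs at n = 24: rejection rate at 0.05 stays nominal
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=24)
            y = rng.normal(size=24)
            hits += simple_regression(y, x).p < 0.05
        rate = hits / reps
        assert 0.017 <= rate <= 0.083  # 3 binomial SDs around 0.05

    def test_zero_variance_x_raises(self):
        with pytest.raises(DegenerateDataError):
            simple_regression([1, 2, 3], [5, 5, 5])


class TestBH:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_empty_family(self):
        assert bh_adjust([]).size == 0

    def test_step_up_oracle(self, rng):
        # independent hand implementation of the step-up rule
        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            order = np.argsort(p)
            m = len(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_properties(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)
        # monotone in p within the family
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        # re-adjusting never lowers a Q value, and constant families
        # (like a fully stepped-up block) are fixed points
        assert np.all(bh_adjust(q) >= q - 1e-12)
        flat = np.full(4, float(q[0]))
        np.testing.assert_allclose(bh_adjust(flat), flat, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestScreen:
    def test_single_x_q_equals_p(self, cohort_df):
        (res,) = screen(cohort_df, "sara", ["aoo"])
        assert res.q == pytest.approx(res.p)

    def test_dispatch_and_family_adjustment(self, cohort_df):
        results = screen(
            cohort_df, "sara", ["aoo", "cd", "ancestry", "sex"],
            var_types={"homozygous": "categorical"},
        )
        kinds = {r.x_var: r.test_name for r in results}
        assert kinds["aoo"] == "regression"
        assert kinds["cd"] in ("t_test", "anova")
        assert kinds["ancestry"] == "anova"
        for r in results:
            assert r.q >= r.p - 1e-12 and r.flagged == (r.q < 0.10)

    def test_categorical_pair_uses_fisher(self, cohort_df):
        (res,) = screen(cohort_df, "cd", ["tr"])
        assert res.test_name == "fisher_exact"

    def test_invariant_to_row_order(self, cohort_df):
        shuffled = cohort_df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = screen(cohort_df, "sara", ["aoo", "cd", "tr"])
        b = screen(shuffled, "sara", ["aoo", "cd", "tr"])
        for ra, rb in zip(a, b):
            assert ra.p == pytest.approx(rb.p, rel=1e-9)

    def test_results_table_shape(self, cohort_df):
        tab = results_table(screen(cohort_df, "sara", ["aoo", "cd"]))
        assert list(tab.columns) == [
            "test_name", "y", "x", "n", "statistic", "p", "q", "flagged",
        ]
        assert len(tab) == 2
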