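import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from carnrec.stats import (
    dunn_posthoc,
    fisher_exact,
    fit_logistic,
    gof_chisq,
    holm_adjust,
    kruskal_wallis,
    posthoc_binomial,
    stepwise_aic,
    stepwise_lrt,
)


def _bernoulli_design(rng, n, k, p=0.4):
    return pd.DataFrame(
        rng.random((n, k)) < p, columns=[f"x{j}" for j in range(k)]
    ).astype(float)


class TestFitLogistic:
    def test_intercept_only_equals_logit_of_mean(self):
        y = np.array([1] * 25 + [0] * 75)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.coef("intercept") == pytest.approx(math.log(1 / 3), abs=1e-6)

    def test_single_binary_slope_equals_log_cross_product_ratio(self):
        a, b, c, d = 30, 10, 20, 40  # y=1/x=1, y=0/x=1, y=1/x=0, y=0/x=0
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        fit = fit_logistic(x, y)
        assert fit.coefficients[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)

    def test_odds_ratio_is_exp_of_coefficient(self):
        rng = np.random.default_rng(0)
        X = _bernoulli_design(rng, 200, 3)
        y = (rng.random(200) < 0.3).astype(float)
        fit = fit_logistic(X, y)
        np.testing.assert_allclose(fit.odds_ratios, np.exp(fit.coefficients), rtol=1e-12)

    def test_ci90_nested_in_ci95(self):
        rng = np.random.default_rng(1)
        X = _bernoulli_design(rng, 300, 4)
        y = (rng.random(300) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        assert (fit.ci90[:, 0] >= fit.ci95[:, 0]).all()
        assert (fit.ci90[:, 1] <= fit.ci95[:, 1]).all()

    def test_aic_identity(self):
        rng = np.random.default_rng(2)
        X = _bernoulli_design(rng, 150, 2)
        y = (rng.random(150) < 0.5).astype(float)
        fit = fit_logistic(X, y)
        assert fit.aic == pytest.approx(2 * len(fit.terms) - 2 * fit.log_likelihood)

    def test_perfect_separation_flagged(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        fit = fit_logistic(x, y)
        assert fit.separation_flag

    def test_zero_variance_response_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_constant_column_warned(self):
        y = np.array([0, 1] * 10, dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            fit_logistic(np.ones((20, 1)), y)


class TestStepwise:
    def _planted(self, seed, n=500, betas=(2.0, 0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        X = _bernoulli_design(rng, n, len(betas))
        eta = -1.0 + X.to_numpy() @ np.asarray(betas)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return X, y

    def test_pure_noise_mostly_reduces_to_intercept(self):
        picks = []
        for seed in range(10):
            X, y = self._planted(seed, n=500, betas=(0.0, 0.0, 0.0))
            fit = stepwise_aic(X, y)
            picks.append(len(fit.terms) - 1)
        assert sum(p == 0 for p in picks) >= 6  # intercept-only in most seeds

    def test_strong_signal_retained(self):
        X, y = self._planted(7, n=2000, betas=(2.0, 0.0, 0.0, 0.0))
        fit = stepwise_aic(X, y)
        assert "x0" in fit.terms

    def test_backward_aic_matches_exhaustive_best_subset(self):
        for seed in range(5):
            X, y = self._planted(seed, n=300, betas=(1.5, 0.8, 0.0, 0.0))
            best_aic = min(
                fit_logistic(X[list(sub)], y).aic if sub else fit_logistic(pd.DataFrame(index=X.index), y).aic
                for r in range(X.shape[1] + 1)
                for sub in itertools.combinations(X.columns, r)
            )
            fit = stepwise_aic(X, y)
            # greedy backward can only match or exceed the exhaustive optimum;
            # on these well-separated designs it should attain it
            assert fit.aic == pytest.approx(best_aic, abs=1e-6)

    def test_lrt_no_qualifying_predictor_gives_intercept_only(self):
        X, y = self._planted(3, n=400, betas=(0.0, 0.0))
        fit = stepwise_lrt(X, y, alpha_enter=1e-6)
        assert fit.terms == ["intercept"]

    def test_nested_lrt_statistic_is_twice_delta_loglik(self):
        X, y = self._planted(11, n=400, betas=(1.0, 0.0))
        full = fit_logistic(X, y)
        reduced = fit_logistic(X[["x0"]], y)
        stat = 2 * (full.log_likelihood - reduced.log_likelihood)
        assert stat >= 0
        assert sps.chi2.sf(stat, 1) == pytest.approx(
            1 - sps.chi2.cdf(stat, 1), abs=1e-12
        )

    def test_aic_and_lrt_agree_on_strong_signal(self):
        X, y = self._planted(13, n=2000, betas=(2.0, 0.0, 0.0))
        assert "x0" in stepwise_aic(X, y).terms
        assert "x0" in stepwise_lrt(X, y).terms


class TestGOF:
    def test_exact_proportions_give_zero_statistic(self):
        res = gof_chisq([10, 20, 30], [1 / 6, 2 / 6, 3 / 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pearson_statistic(self):
        res = gof_chisq([10, 20, 30], [1 / 3, 1 / 3, 1 / 3])
        assert res.statistic == pytest.approx(10.0)
        assert res.method == "asymptotic"

    def test_small_expected_triggers_monte_carlo(self):
        res = gof_chisq([2, 48, 50], [0.03, 0.47, 0.5], seed=0)
        assert res.method == "monte_carlo"
        assert 0 < res.p_value <= 1

    def test_mc_agrees_with_asymptotic_at_large_counts(self):
        obs = [90, 110, 100]
        props = [1 / 3, 1 / 3, 1 / 3]
        asym = gof_chisq(obs, props)
        mc = gof_chisq(obs, props, mc_threshold=1e9, seed=5, n_sim=20000)
        assert mc.method == "monte_carlo"
        assert mc.p_value == pytest.approx(asym.p_value, abs=0.02)

    def test_zero_total_count_errors(self):
        with pytest.raises(ValueError):
            gof_chisq([0, 0], [0.5, 0.5], seed=0)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            gof_chisq([5, 5], [0.4, 0.4])


class TestHolmPosthoc:
    def test_holm_matches_brute_force_step_down(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.random(rng.integers(1, 8))
            adj = holm_adjust(p)
            # brute force: sort, multiply by (m - i), enforce monotone, cap
            order = np.argsort(p)
            m = len(p)
            brute = np.empty(m)
            prev = 0.0
            for i, idx in enumerate(order):
                val = max(prev, (m - i) * p[idx])
                brute[idx] = min(1.0, val)
                prev = val
            np.testing.assert_allclose(adj, brute)

    def test_adjusted_monotone_in_raw_order(self):
        p = np.array([0.001, 0.04, 0.02, 0.5, 0.3])
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_single_test_unchanged(self):
        tests = posthoc_binomial([5], 20, [0.25])
        assert tests[0].p_adjusted == pytest.approx(tests[0].binomial_p_raw)

    def test_observed_at_expectation_not_significant(self):
        n = 100
        props = [0.2, 0.3, 0.5]
        obs = [round(n * p) for p in props]
        tests = posthoc_binomial(obs, n, props)
        assert all(not t.significant for t in tests)
        assert all(t.binomial_p_raw > 0.5 for t in tests)

    def test_adjusted_at_least_raw(self):
        tests = posthoc_binomial([30, 5, 65], 100, [0.2, 0.3, 0.5])
        for t in tests:
            assert t.p_adjusted >= t.binomial_p_raw

    def test_doubling_rule_differs_but_valid(self):
        a = posthoc_binomial([3], 40, [0.25], rule="min_likelihood")[0]
        b = posthoc_binomial([3], 40, [0.25], rule="doubling")[0]
        assert 0 < a.binomial_p_raw <= 1 and 0 < b.binomial_p_raw <= 1


def _enumerate_fisher(table):
    """Full enumeration oracle: sum probabilities of all tables with the
    observed margins whose probability <= observed (minimum-likelihood rule)."""
    from carnrec.stats import _log_table_prob

    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    obs_lp = _log_table_prob(t)
    nr, nc = t.shape
    total = 0.0
    extreme = 0.0

    def rec_fill(i, remaining_cols, out_rows):
        nonlocal total, extreme
        if i == nr - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            cand = np.vstack(out_rows + [last])
            lp = _log_table_prob(cand)
            p = math.exp(lp)
            total += p
            if lp <= obs_lp + 1e-9:
                extreme += p
            return
        # enumerate row i compositions summing to rows[i], bounded by remaining
        def comp(j, left, row):
            if j == nc - 1:
                if left <= remaining_cols[j]:
                    rec_fill(i + 1, remaining_cols - np.array(row + [left]), out_rows + [np.array(row + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                comp(j + 1, left - v, row + [v])

        comp(0, rows[i], [])

    rec_fill(0, cols.copy(), [])
    assert total == pytest.approx(1.0, abs=1e-9)
    return extreme


class TestFisherExact:
    def test_2x2_enumeration_value(self):
        table = [[1, 9], [11, 3]]
        p = fisher_exact(table)
        assert p == pytest.approx(_enumerate_fisher(table), abs=1e-9)
        assert p == pytest.approx(0.0028, abs=2e-4)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact([[8, 12], [8, 12]]) == pytest.approx(1.0)

    def test_3x3_monte_carlo_near_enumeration(self):
        table = [[4, 1, 0], [1, 3, 1], [0, 1, 4]]
        exact = _enumerate_fisher(table)
        mc = fisher_exact(table, n_sim=40000, seed=7)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact([[0, 0], [3, 4]])


class TestKruskalDunn:
    def test_identical_constant_groups(self):
        H, df, p = kruskal_wallis([[3, 3, 3], [3, 3], [3, 3, 3, 3]])
        assert (H, df, p) == (0.0, 2, 1.0)

    def test_two_groups_equals_squared_ranksum_z(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        H, df, p = kruskal_wallis([a, b])
        # Wilcoxon rank-sum normal approximation without continuity correction
        n1, n2 = len(a), len(b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        w = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2
        sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (w - mu) / sigma
        assert H == pytest.approx(z**2, rel=1e-10)

    def test_hand_computed_three_groups(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]  # no ties; ranks known exactly
        H, df, p = kruskal_wallis(groups)
        n = 9
        rank_sums = [6, 15, 24]
        expected = 12 / (n * (n + 1)) * sum(rs**2 / 3 for rs in rank_sums) - 3 * (n + 1)
        assert H == pytest.approx(expected, rel=1e-10)
        assert df == 2

    def test_dunn_identical_groups_z_zero(self):
        res = dunn_posthoc([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]])
        assert res["z"].iloc[0] == pytest.approx(0.0)
        assert res["p_adjusted"].iloc[0] == pytest.approx(1.0)

    def test_dunn_emits_all_pairs(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(i, 1, 8) for i in range(4)]
        res = dunn_posthoc(groups)
        assert len(res) == 4 * 3 // 2

    def test_dunn_holm_matches_oracle(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(i * 0.7, 1, 10) for i in range(3)]
        res = dunn_posthoc(groups, adjustment="holm")
        np.testing.assert_allclose(
            res["p_adjusted"].to_numpy(), holm_adjust(res["p_raw"].to_numpy())
        )
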