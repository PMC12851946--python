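import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spinepath.survstats import (
    bootstrap_ci,
    concordance,
    cox_fit,
    group_tests,
    km_estimate,
    logrank_test,
)


def brute_force_concordance(risk, time, event):
    """Independent all-pairs oracle (Harrell, 0.5 tie credit)."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if event[i] == 1 and (time[i] < time[j] or (time[i] == time[j] and event[j] == 0)):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den if den else np.nan


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_curve(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.survival_at(10) == 1.0

    def test_mixed_case_matches_hand_product_limit(self):
        # times 1+,2,2,3+,4,5 (+ censored): hand computation
        # t=2: S = 1 - 2/5 = 0.6 ; t=4: S = 0.6 * (1 - 1/2) = 0.3
        # t=5: S = 0.3 * (1 - 1/1) = 0.0
        km = km_estimate([1, 2, 2, 3, 4, 5], [0, 1, 1, 0, 1, 1])
        assert np.allclose(km.times, [2, 4, 5])
        assert np.allclose(km.survival, [0.6, 0.3, 0.0])

    def test_monotone_and_ci_contains_estimate(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        e[0] = 1
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.ci_lower - 1e-12 <= km.survival) & (km.survival <= km.ci_upper + 1e-12)).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError):
            km_estimate([1.0, 2.0], [1, 2])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_eight_sample_hand_tabulation(self):
        # group A: 1, 2, 3+, 4 ; group B: 3, 5, 6+, 7
        ta, ea = [1, 2, 3, 4], [1, 1, 0, 1]
        tb, eb = [3, 5, 6, 7], [1, 1, 0, 1]
        chi2, p = logrank_test(ta, ea, tb, eb)
        # independent tabulation of O-E and V at each event time
        o_e, v = 0.0, 0.0
        all_t = np.array(ta + tb, float)
        all_e = np.array(ea + eb)
        grp = np.array([0] * 4 + [1] * 4)
        for t in sorted(set(all_t[all_e == 1])):
            at = all_t >= t
            n, nb = at.sum(), (at & (grp == 1)).sum()
            died = (all_t == t) & (all_e == 1)
            d, db = died.sum(), (died & (grp == 1)).sum()
            o_e += db - d * nb / n
            if n > 1:
                v += d * (nb / n) * (1 - nb / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(o_e**2 / v, rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(10, 40), rng.exponential(20, 40)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        ea[0] = eb[0] = 1
        chi2, p = logrank_test(ta, ea, tb, eb)
        res = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_invariant_under_monotone_time_rescaling(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(5, 30), rng.exponential(9, 30)
        ea, eb = np.ones(30, int), rng.integers(0, 2, 30)
        c1 = logrank_test(ta, ea, tb, eb)
        c2 = logrank_test(np.sqrt(ta), ea, np.sqrt(tb), eb)
        assert c1[0] == pytest.approx(c2[0], rel=1e-12)

    def test_power_under_planted_hazard_ratio(self):
        rng = np.random.default_rng(3)
        sig = 0
        n_sim = 60
        for _ in range(n_sim):
            ta = rng.exponential(1.0, 75)
            tb = rng.exponential(3.0, 75)  # hazard ratio 3
            ca = rng.exponential(5.0, 75)
            cb = rng.exponential(15.0, 75)
            ea, eb = (ta <= ca).astype(int), (tb <= cb).astype(int)
            _, p = logrank_test(np.minimum(ta, ca), ea, np.minimum(tb, cb), eb)
            sig += p < 0.001
        assert sig / n_sim >= 0.95

    def test_no_events_warns_nan(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(p)


class TestCox:
    def test_planted_beta_recovered(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.normal(size=n)
        u = rng.random(n)
        t = -np.log(u) / np.exp(0.7 * x)
        cov = pd.DataFrame({"x": x})
        res = cox_fit(t, np.ones(n, int), cov)
        assert abs(res.coef["x"] - 0.7) < 0.15

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(6)
        covered = 0
        n_sim = 60
        for _ in range(n_sim):
            x = rng.normal(size=120)
            t = rng.exponential(1.0, 120)
            res = cox_fit(t, np.ones(120, int), pd.DataFrame({"x": x}))
            covered += res.ci_lower["x"] <= 1.0 <= res.ci_upper["x"]
        assert 0.85 <= covered / n_sim <= 1.0

    def test_matches_partial_likelihood_grid_search(self):
        # tiny dataset, single binary covariate, no ties
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def neg_log_pl(beta):
            order = np.argsort(t)
            ll = 0.0
            for k, i in enumerate(order):
                risk = order[k:]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        grid = np.linspace(-3, 3, 6001)
        beta_grid = grid[np.argmin([neg_log_pl(b) for b in grid])]
        res = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert abs(res.coef["x"] - beta_grid) < 2e-3

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert concordance(risk, t, np.ones(5, int)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1, 500)
        r = rng.normal(size=500)
        assert abs(concordance(r, t, np.ones(500, int)) - 0.5) < 0.03

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        t = np.round(rng.exponential(5, n), 1) + 0.1  # induce ties
        e = rng.integers(0, 2, n)
        e[:2] = 1
        r = np.round(rng.normal(size=n), 1)  # induce score ties
        assert concordance(r, t, e) == pytest.approx(
            brute_force_concordance(r, t, e), abs=1e-12
        )

    def test_no_admissible_pairs_nan(self):
        assert np.isnan(concordance([1.0, 2.0], [1.0, 2.0], [0, 0]))


class TestGroupTests:
    def test_u_statistic_enumeration(self):
        report = group_tests([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        # scipy's U is for the first group: all 9 pairs lose -> U in {0, 9}
        assert report["mannwhitney_u"] in (0.0, 9.0)

    def test_kruskal_for_three_groups(self):
        vals = [1, 2, 3, 10, 11, 12, 20, 21, 22]
        grp = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        report = group_tests(vals, grp)
        assert report["kruskal_p"] < 0.05

    def test_spearman_of_monotone_pairing_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        y = np.exp(x)
        report = group_tests(
            [1, 2, 3, 4], ["a", "a", "b", "b"], correlations={"xy": (x, y)}
        )
        assert report["xy_spearman_rho"] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            a, b = rng.normal(size=25), rng.normal(size=25)
            ps.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1, 2, 3], ["a", "a", "b"])

    def test_bh_adjustment_present(self):
        report = group_tests(
            [1, 2, 3, 4], ["a", "a", "b", "b"], correlations={"xy": ([1, 2, 3], [2, 4, 6])}
        )
        assert set(report["bh_adjusted"]) == {"mannwhitney_p", "xy_pearson_p", "xy_spearman_p"}


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        est, (lo, hi) = bootstrap_ci(lambda d: 3.5, np.arange(50), n_boot=200, seed=0)
        assert est == 3.5 and lo == hi == 3.5

    def test_normal_mean_ci_width_matches_clt(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=200)
        est, (lo, hi) = bootstrap_ci(np.mean, data, n_boot=1000, seed=1)
        expected = 2 * 1.96 / np.sqrt(200)
        assert abs((hi - lo) - expected) / expected < 0.2

    def test_seed_reproducibility(self):
        data = np.random.default_rng(10).normal(size=100)
        r1 = bootstrap_ci(np.mean, data, n_boot=300, seed=4)
        r2 = bootstrap_ci(np.mean, data, n_boot=300, seed=4)
        assert r1 == r2

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.arange(10), n_boot=50)

    def test_undefined_resamples_redrawn_then_capped(self):
        def metric(d):
            return np.nan

        with pytest.raises(RuntimeError, match="too many"):
            bootstrap_ci(metric, np.arange(10), n_boot=100, seed=0, max_redraws=50)
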