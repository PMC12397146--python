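"""Segmented regression, Davies test, resampling inference, LMG."""

import itertools

import numpy as np
import pytest

import limnotrends as lt
from limnotrends import (
    bootstrap_slope_ci,
    davies_test,
    detrended_lag1,
    fit_segmented,
    lmg_importance,
    pearson_cor,
    permutation_slope_test,
    select_trend_model,
)


def piecewise(x, psi=25.0, left=-1.0, right=2.0, intercept=10.0):
    return intercept + np.where(x < psi, left * (x - psi), right * (x - psi))


class TestFitSegmented:
    def test_noiseless_break_recovered_exactly(self):
        x = np.arange(50, dtype=float)
        fit = fit_segmented(x, piecewise(x))
        assert fit.converged
        assert fit.psi == pytest.approx(25.0, abs=1e-8)
        assert fit.left_slope == pytest.approx(-1.0, abs=1e-8)
        assert fit.right_slope == pytest.approx(2.0, abs=1e-8)

    def test_straight_line_is_non_identifiable(self):
        x = np.arange(50, dtype=float)
        fit = fit_segmented(x, 2.0 * x + 3.0)
        assert fit.boundary and not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(lt.ValidationError):
            fit_segmented(np.arange(5.0), np.arange(5.0) ** 2)

    def test_psi_strictly_interior(self):
        rng = np.random.default_rng(11)
        x = np.arange(30, dtype=float)
        for _ in range(20):
            fit = fit_segmented(x, rng.normal(0, 1, 30))
            if fit.converged:
                assert np.sort(x)[2] < fit.psi < np.sort(x)[-3]


class TestDaviesTest:
    def test_strong_break_detected(self):
        rng = np.random.default_rng(1)
        x = np.arange(50, dtype=float)
        assert davies_test(x, piecewise(x) + rng.normal(0, 0.1, 50)) < 0.01

    def test_constant_response_gives_one(self):
        assert davies_test(np.arange(50.0), np.ones(50)) == 1.0

    def test_too_few_candidates_rejected(self):
        with pytest.raises(lt.ValidationError):
            davies_test(np.arange(20.0), np.arange(20.0), k=1)

    def test_plain_line_not_flagged(self):
        rng = np.random.default_rng(5)
        x = np.arange(40, dtype=float)
        p = davies_test(x, 0.5 * x + rng.normal(0, 1, 40))
        assert p > 0.05


class TestPermutationSlopeTest:
    def test_constant_y(self):
        assert permutation_slope_test(np.arange(5.0), np.ones(5)) == 1.0

    def test_small_n_matches_exhaustive_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 3.5, 4.0, 6.0, 9.0])
        xc = x - x.mean()
        b_obs = abs(np.dot(xc, y) / np.dot(xc, xc))
        count = sum(
            abs(np.dot(xc, p) / np.dot(xc, xc)) >= b_obs - 1e-12
            for p in itertools.permutations(y)
        )
        want = count / 120
        assert permutation_slope_test(x, y, b=10_000, seed=0) == pytest.approx(want)

    def test_perfect_monotone_n5(self):
        p = permutation_slope_test(np.arange(5.0), np.arange(5.0) * 2 + 1)
        assert p == pytest.approx(2 / 120)  # identity and reversal only

    def test_reproducible_and_shift_invariant(self):
        rng = np.random.default_rng(2)
        x = np.arange(20, dtype=float)
        y = 0.3 * x + rng.normal(0, 1, 20)
        p1 = permutation_slope_test(x, y, b=999, seed=42)
        p2 = permutation_slope_test(x, y, b=999, seed=42)
        p3 = permutation_slope_test(x + 1900, y, b=999, seed=42)
        assert p1 == p2 == p3


class TestBootstrapSlopeCI:
    def test_noiseless_line_collapses(self):
        x = np.arange(20, dtype=float)
        lo, hi = bootstrap_slope_ci(x, 2.0 * x - 1.0, b=200, seed=0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        x = np.arange(40, dtype=float)
        y = 1.5 * x + rng.normal(0, 3, 40)
        slope = np.polyfit(x, y, 1)[0]
        lo, hi = bootstrap_slope_ci(x, y, b=999, seed=5)
        assert lo <= slope <= hi

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x = np.arange(30, dtype=float)
        y = x + rng.normal(0, 1, 30)
        assert bootstrap_slope_ci(x, y, b=500, seed=9) == bootstrap_slope_ci(
            x, y, b=500, seed=9
        )


class TestSelectTrendModel:
    def test_clear_break_selected_by_davies_rule(self):
        rng = np.random.default_rng(6)
        x = np.arange(50, dtype=float)
        res = select_trend_model(x, piecewise(x) + rng.normal(0, 1, 50), b=199, seed=1)
        assert res.kind == "segmented"
        assert "davies" in res.decision and "-> segmented" in res.decision
        assert res.davies_p < 0.05

    def test_weak_break_selected_by_aic_rule(self):
        # davies fails at alpha=0.05 but the AIC prefers the breakpoint model
        rng = np.random.default_rng(9)
        x = np.arange(30, dtype=float)
        y = np.where(x < 15, 0.0, 0.35 * (x - 15)) + rng.normal(0, 1.0, 30)
        res = select_trend_model(x, y, b=99, seed=1)
        assert res.kind == "segmented"
        assert res.davies_p >= 0.05
        assert res.aic_segmented < res.aic_linear
        assert "AIC" in res.decision

    def test_null_mostly_stays_linear(self):
        # the Davies(0.05)-then-AIC cascade keeps an irreducible ~12% null
        # selection rate (~5% Davies + ~7% AIC), so conservatism is bounded
        # below by 80%, not by 1 - alpha
        rng = np.random.default_rng(0)
        x = np.arange(40, dtype=float)
        kinds = [
            select_trend_model(x, 0.4 * x + rng.normal(0, 1, 40), b=49, seed=0).kind
            for _ in range(200)
        ]
        assert kinds.count("linear") / 200 >= 0.80

    def test_constant_response_short_circuits_to_linear(self):
        res = select_trend_model(np.arange(20.0), np.full(20, 3.3), b=49, seed=0)
        assert res.kind == "linear"
        assert res.decision.startswith("constant")


class TestCorrelations:
    def test_exact_linear_relation(self):
        a = np.arange(10.0)
        assert pearson_cor(a, 2 * a + 1)[0] == pytest.approx(1.0)
        assert pearson_cor(a, -a)[0] == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        r, _ = pearson_cor(a, b)
        assert r == pytest.approx(1.0)

    def test_zero_variance_missing(self):
        r, p = pearson_cor(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)


class TestDetrendedLag1:
    def test_perfect_linear_series_missing(self):
        years = np.arange(1990, 2010)
        r, p = detrended_lag1(years, 2.0 * years + 3.0)
        assert np.isnan(r) and np.isnan(p)

    def test_ar1_process_recovered(self):
        rng = np.random.default_rng(10)
        n = 5000
        eps = rng.normal(0, 1, n)
        resid = np.empty(n)
        resid[0] = eps[0]
        for t in range(1, n):
            resid[t] = 0.5 * resid[t - 1] + eps[t] * np.sqrt(1 - 0.25)
        years = np.arange(n)
        r, p = detrended_lag1(years, 0.1 * years + resid)
        assert r == pytest.approx(0.5, abs=0.05)
        assert p < 1e-6

    def test_gap_pairs_dropped(self):
        rng = np.random.default_rng(12)
        years = np.array(list(range(1990, 2000)) + list(range(2005, 2015)))
        vals = rng.normal(0, 1, years.size)
        r_gap, _ = detrended_lag1(years, vals)
        # manual check: same residuals, only consecutive-year pairs
        slope = np.polyfit(years, vals, 1)
        resid = vals - np.polyval(slope, years)
        keep = np.diff(years) == 1
        want, _ = pearson_cor(resid[:-1][keep], resid[1:][keep])
        assert r_gap == pytest.approx(want, rel=1e-12)


def shapley_oracle(y, xmat):
    """Independent LMG via the subset-weighted (Shapley) formula."""
    import math

    n, p = xmat.shape

    def r2(cols):
        if not cols:
            return 0.0
        design = np.column_stack([np.ones(n), xmat[:, sorted(cols)]])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - resid @ resid / tss

    shares = []
    for j in range(p):
        total = 0.0
        others = [k for k in range(p) if k != j]
        for size in range(p):
            for subset in itertools.combinations(others, size):
                w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
                total += w * (r2(set(subset) | {j}) - r2(set(subset)))
        shares.append(total)
    return np.array(shares)


class TestLMGImportance:
    def test_single_predictor_share_is_r2(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 40)
        y = 2 * x + rng.normal(0, 1, 40)
        imp = lmg_importance(y, {"x": x})
        assert imp.shares["x"] == pytest.approx(imp.r_squared, rel=1e-12)

    def test_orthogonal_predictors_get_marginal_r2(self):
        x1 = np.tile([1.0, -1.0], 32)
        x2 = np.repeat([1.0, -1.0], 32)
        rng = np.random.default_rng(14)
        y = 2 * x1 + x2 + rng.normal(0, 0.5, 64)

        def marginal(x):
            r, _ = pearson_cor(x, y)
            return r**2

        imp = lmg_importance(y, {"a": x1, "b": x2})
        assert imp.shares["a"] == pytest.approx(marginal(x1), abs=1e-10)
        assert imp.shares["b"] == pytest.approx(marginal(x2), abs=1e-10)

    def test_matches_shapley_oracle_on_correlated_design(self):
        rng = np.random.default_rng(15)
        z = rng.normal(0, 1, 40)
        xmat = np.column_stack(
            [z + rng.normal(0, 0.5, 40), z + rng.normal(0, 0.8, 40), rng.normal(0, 1, 40)]
        )
        y = xmat @ [1.0, -0.5, 0.3] + rng.normal(0, 1, 40)
        imp = lmg_importance(y, {"a": xmat[:, 0], "b": xmat[:, 1], "c": xmat[:, 2]})
        want = shapley_oracle(y, xmat)
        np.testing.assert_allclose(
            [imp.shares["a"], imp.shares["b"], imp.shares["c"]], want, rtol=1e-9
        )
        assert sum(imp.shares.values()) == pytest.approx(imp.r_squared, abs=1e-9)
        assert all(v >= 0 for v in imp.shares.values())

    def test_share_order_invariant(self):
        rng = np.random.default_rng(16)
        x1, x2 = rng.normal(0, 1, (2, 30))
        y = x1 + 0.5 * x2 + rng.normal(0, 1, 30)
        a = lmg_importance(y, {"x1": x1, "x2": x2})
        b = lmg_importance(y, {"x2": x2, "x1": x1})
        assert a.shares["x1"] == pytest.approx(b.shares["x1"], rel=1e-12)

    def test_rank_deficient_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(lt.ValidationError):
            lmg_importance(np.arange(20.0), {"a": x, "b": 2 * x})
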