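"""Density, Schmidt stability, critical stability and phenology."""

import datetime as dt

import numpy as np
import pytest
from scipy.integrate import simpson

import limnotrends as lt
from limnotrends.stratification import (
    GRAVITY,
    CriticalStabilityConfig,
    DailyTemperatureGrid,
    stratification_seasons,
)


def simpson_oracle(depths, temps, hyp, h=0.01):
    """Independent 1-cm-grid quadrature of the stability integral.

    Integrates segment by segment (segments delimited by temperature and
    hypsography knots, so each piece is smooth) with scipy's Simpson rule.
    """
    depths = np.asarray(depths, float)
    temps = np.asarray(temps, float)
    zmax = hyp.max_depth
    knots = np.unique(np.concatenate([[0.0, zmax], depths, hyp.depths]))
    # volume-weighted mean depth on a fine grid
    zf = np.linspace(0, zmax, int(zmax / 0.001) + 1)
    af = hyp.area_at(zf)
    zv = simpson(zf * af, x=zf) / simpson(af, x=zf)

    def temp_at(z, side):
        # piecewise linear; duplicated depths are a step discontinuity
        if z <= depths[0]:
            return temps[0]
        if z >= depths[-1]:
            return temps[-1]
        idx = np.searchsorted(depths, z, side="left" if side == "-" else "right")
        i1 = min(max(idx, 1), len(depths) - 1)
        z0, z1, t0, t1 = depths[i1 - 1], depths[i1], temps[i1 - 1], temps[i1]
        if z1 == z0:
            return t0 if side == "-" else t1
        return t0 + (t1 - t0) * (z - z0) / (z1 - z0)

    total = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        if b - a <= 0:
            continue
        n = max(2, int(np.ceil((b - a) / h)))
        zz = np.linspace(a, b, 2 * n + 1)
        tt = np.array(
            [temp_at(z, "+") if z > a else temp_at(z, "+") for z in zz]
        )
        tt[-1] = temp_at(b, "-")
        rho = lt.water_density(np.clip(tt, 0, 40))
        total += simpson((zz - zv) * rho * hyp.area_at(zz), x=zz)
    return GRAVITY / hyp.surface_area * total


class TestWaterDensity:
    def test_maximum_near_3_98(self):
        t = np.linspace(0, 40, 4001)
        assert t[np.argmax(lt.water_density(t))] == pytest.approx(3.98, abs=0.02)

    def test_cold_water_ordering(self):
        assert lt.water_density(4.0) > lt.water_density(6.0) > lt.water_density(20.0)

    def test_reference_value_at_20(self):
        assert lt.water_density(20.0) == pytest.approx(998.2, abs=0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(lt.ValidationError):
            lt.water_density(-5.0)


class TestSchmidtStability:
    def test_isothermal_is_zero(self, cone):
        s = lt.schmidt_stability([0.0, 5.0, 10.0], [10.0, 10.0, 10.0], cone)
        assert abs(s) < 1e-9

    def test_two_layer_cylinder_matches_oracle(self, cylinder):
        depths = [0.0, 5.0, 5.0, 10.0]
        temps = [6.0, 6.0, 4.0, 4.0]
        got = lt.schmidt_stability(depths, temps, cylinder)
        want = simpson_oracle(depths, temps, cylinder)
        assert got == pytest.approx(want, rel=1e-6)

    def test_smooth_profile_cone_matches_oracle(self, deep_cone):
        depths = np.arange(0.0, 25.0, 3.0)
        temps = 4.0 + 16.0 / (1.0 + np.exp((depths - 11.0) / 1.5))
        got = lt.schmidt_stability(depths, temps, deep_cone)
        want = simpson_oracle(depths, temps, deep_cone)
        assert got == pytest.approx(want, rel=1e-6)

    def test_single_depth_rejected(self, cone):
        with pytest.raises(lt.ValidationError):
            lt.schmidt_stability([5.0], [10.0], cone)

    def test_warming_top_of_stable_column_raises_s(self, basin):
        depths = [0.0, 14.0, 14.0, 25.0]
        prev = -np.inf
        for top in (6.0, 8.0, 12.0, 20.0):
            s = lt.schmidt_stability(depths, [top, top, 4.0, 4.0], basin)
            assert s > prev
            prev = s

    def test_vectorised_matches_per_profile(self, basin):
        rng = np.random.default_rng(7)
        depths = np.arange(0.0, 25.0, 3.0)
        many = 4.0 + rng.uniform(0, 18, size=(5, depths.size))
        batch = lt.schmidt_stability(depths, many, basin)
        single = [lt.schmidt_stability(depths, row, basin) for row in many]
        np.testing.assert_allclose(batch, single, rtol=1e-12)


class TestCriticalStability:
    def test_equal_temperatures_give_zero(self, cylinder):
        cfg = CriticalStabilityConfig(6.0, 6.0, 5.0)
        assert abs(lt.critical_stability(cylinder, cfg)) < 1e-9

    def test_equals_two_layer_schmidt_exactly(self, basin):
        cfg = CriticalStabilityConfig(6.0, 4.0, 14.0)
        direct = lt.schmidt_stability(
            [0.0, 14.0, 14.0, 25.0], [6.0, 6.0, 4.0, 4.0], basin
        )
        assert lt.critical_stability(basin, cfg) == direct

    def test_matches_oracle_on_toys(self, cylinder, cone, basin):
        for hyp, boundary in ((cylinder, 5.0), (cone, 4.0), (basin, 14.0)):
            cfg = CriticalStabilityConfig(6.0, 4.0, boundary)
            got = lt.critical_stability(hyp, cfg)
            want = simpson_oracle(
                [0.0, boundary, boundary, hyp.max_depth], [6.0, 6.0, 4.0, 4.0], hyp
            )
            assert got == pytest.approx(want, rel=1e-6)
            assert got > 0

    def test_boundary_beyond_bottom_rejected(self, cone):
        with pytest.raises(lt.ValidationError):
            lt.critical_stability(cone, CriticalStabilityConfig(6.0, 4.0, 12.0))


def _monthly_profiles(temp_fn, year=2000, depths=(0.0, 12.0, 24.0), n_months=24):
    profiles = []
    for k in range(n_months):
        date = dt.date(year + k // 12, k % 12 + 1, 15)
        t = date.toordinal()
        profiles.append(
            lt.DepthProfile(
                date,
                np.asarray(depths),
                {"temp_c": np.array([temp_fn(t, z) for z in depths])},
            )
        )
    return profiles


class TestInterpolateDaily:
    def test_passes_through_observations(self):
        rng = np.random.default_rng(0)
        vals = {}

        def f(t, z):
            return vals.setdefault((t, z), 4.0 + rng.uniform(0, 15))

        profiles = _monthly_profiles(f)
        grid = lt.interpolate_daily(profiles)
        for p in profiles:
            t = np.datetime64(p.date, "D")
            if grid.dates[0] <= t <= grid.dates[-1]:
                row = grid.temps[np.searchsorted(grid.dates, t)]
                np.testing.assert_allclose(row, p.analyte("temp_c"), atol=1e-8)

    def test_linear_data_reproduced_exactly(self):
        t0 = dt.date(2000, 1, 15).toordinal()
        profiles = _monthly_profiles(lambda t, z: 5.0 + 0.01 * (t - t0) + 0.1 * z)
        grid = lt.interpolate_daily(profiles)
        days = grid.dates.astype(int).astype(float)
        for j, z in enumerate(grid.depths):
            expect = 5.0 + 0.01 * (days - np.datetime64(dt.date(2000, 1, 15)).astype(int)) + 0.1 * z
            np.testing.assert_allclose(grid.temps[:, j], expect, atol=1e-7)

    def test_monthly_sinusoid_recovered_within_tolerance(self):
        def f(t, z):
            return 12.0 + 8.0 * np.sin(2 * np.pi * t / 365.2425)

        profiles = _monthly_profiles(f, n_months=36)
        grid = lt.interpolate_daily(profiles)
        days = grid.dates.astype(int).astype(float)
        truth = 12.0 + 8.0 * np.sin(2 * np.pi * days / 365.2425)
        # exclude the natural-spline edge months from the comparison
        inner = slice(40, -40)
        err = np.max(np.abs(grid.temps[inner, 0] - truth[inner]))
        assert err < 0.2

    def test_few_points_fall_back_to_linear_with_warning(self):
        profiles = _monthly_profiles(lambda t, z: 6.0, n_months=3)
        with pytest.warns(UserWarning, match="support points"):
            grid = lt.interpolate_daily(profiles)
        np.testing.assert_allclose(grid.temps, 6.0)


class TestStratificationSeasons:
    def _dates(self, year):
        start = np.datetime64(f"{year}-01-01")
        n = (np.datetime64(f"{year + 1}-01-01") - start).astype(int)
        return start + np.arange(n)

    def test_above_all_year(self):
        dates = self._dates(2001)
        season = lt.stratification_period(dates, np.full(dates.size, 5.0), 1.0, 2001)
        assert season.duration_days == 365

    def test_longest_run_selected(self):
        dates = self._dates(2001)
        s = np.zeros(dates.size)
        s[10:40] = 5.0  # 30-day winter-ish run
        s[100:220] = 5.0  # 120-day summer run
        season = lt.stratification_period(dates, s, 1.0, 2001)
        assert season.duration_days == 120
        assert season.onset == dt.date(2001, 4, 11)

    def test_never_stratified(self):
        dates = self._dates(2001)
        season = lt.stratification_period(dates, np.zeros(dates.size), 1.0, 2001)
        assert season.duration_days == 0
        assert season.onset is None and season.end is None

    def test_tie_with_s_crit_counts_as_mixed(self):
        dates = self._dates(2001)
        season = lt.stratification_period(dates, np.full(dates.size, 1.0), 1.0, 2001)
        assert season.duration_days == 0

    def test_new_year_run_assigned_by_midpoint(self):
        start = np.datetime64("2001-11-01")
        dates = start + np.arange(150)
        s = np.full(dates.size, 5.0)  # one run from Nov 1 to Mar 30
        seasons = stratification_seasons(dates, s, 1.0)
        assert seasons[2002].duration_days == 150
        assert seasons[2001].duration_days == 0
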