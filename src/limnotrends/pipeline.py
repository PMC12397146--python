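"""End-to-end analysis: dataset -> annual metrics -> trends -> feedback
-> variance partitioning.

Stage order mirrors the scientific workflow: stratification phenology
first (it defines every seasonal window), then the anoxic factor,
volume-weighted seasonal concentrations and rates, withdrawal
accounting, per-series trend selection, the fixed set of causal-pair
correlations, detrended lag-1 feedback checks, and finally a multiple
regression of the anoxic factor on its three candidate drivers with LMG
importance shares. A stage that fails marks itself and its dependents
as failed; independent stages still run.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import anoxia as anoxia_mod
from . import chemistry, hypsometry, stratification, trends, withdrawal
from .config import AnalysisConfig
from .data_model import LakeDataset, LayerSpec, ValidationError

#: causal pairs reported in the correlation table (config-extensible)
CORRELATION_PAIRS = (
    ("af", "tp_hypo"),
    ("af", "tea_hypo"),
    ("af", "duration"),
    ("tp_epi", "chla_epi"),
    ("tp_hypo", "tp_epi"),
)

#: annual series that get a linear-vs-segmented trend decision
TREND_SERIES = (
    "af",
    "tp_hypo",
    "tp_epi",
    "chla_epi",
    "o2_hypo",
    "tea_hypo",
    "nh4_hypo",
    "duration",
    "inflow_tp",
    "o2_rate",
    "tea_rate",
    "nh4_rate",
    "hw_reduction",
)


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance."""

    annual_metrics: pd.DataFrame
    trend_table: pd.DataFrame
    correlation_table: pd.DataFrame
    lag1: dict
    effectiveness: dict
    lmg: dict | None
    trend_results: dict
    provenance: dict
    failures: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.annual_metrics.to_csv(outdir / "annual_metrics.csv", index=False)
        self.trend_table.to_csv(outdir / "trends.csv", index=False)
        self.correlation_table.to_csv(outdir / "correlations.csv", index=False)
        if self.lmg is not None:
            pd.DataFrame(
                [
                    {
                        "predictor": k,
                        "lmg_share": v,
                        "share_of_r2_pct": 100.0 * v / self.lmg["r_squared"]
                        if self.lmg["r_squared"] > 0
                        else float("nan"),
                    }
                    for k, v in self.lmg["shares"].items()
                ]
            ).to_csv(outdir / "lmg.csv", index=False)
        report = {
            "provenance": self.provenance,
            "lag1": self.lag1,
            "effectiveness": self.effectiveness,
            "lmg": self.lmg,
            "failures": self.failures,
        }
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)


def _profile_series(dataset: LakeDataset, analyte: str, layer: LayerSpec):
    """Per-profile volume-weighted layer mean of one analyte."""
    dates, vals = [], []
    for p in dataset.profiles:
        if not p.has(analyte):
            continue
        v = hypsometry.volume_weighted_mean(
            p.depths, p.analyte(analyte), dataset.hypsography, layer
        )
        dates.append(p.date)
        vals.append(v)
    return dates, np.asarray(vals, dtype=float)


def _tea_profile_series(dataset: LakeDataset, layer: LayerSpec, weights):
    dates, vals = [], []
    for p in dataset.profiles:
        if not (p.has("so4_mmol_l") and p.has("no3_mmol_l")):
            continue
        so4 = hypsometry.volume_weighted_mean(
            p.depths, p.analyte("so4_mmol_l"), dataset.hypsography, layer
        )
        no3 = hypsometry.volume_weighted_mean(
            p.depths, p.analyte("no3_mmol_l"), dataset.hypsography, layer
        )
        if np.isfinite(so4) and np.isfinite(no3):
            dates.append(p.date)
            vals.append(chemistry.tea_concentration(so4, no3, weights))
    return dates, np.asarray(vals, dtype=float)


def _seasonal_means(dates, values, seasons) -> dict[int, float]:
    out = {}
    for year, season in seasons.items():
        summary = chemistry.seasonal_summary(dates, values, season, "mean")
        out[year] = summary.value
    return out


def _rates(dates, values, seasons, analyte: str, oxygen_max_points: int) -> dict[int, float]:
    out = {}
    for year, season in seasons.items():
        if season.onset is None:
            out[year] = float("nan")
            continue
        t0 = season.onset.toordinal()
        sel = [
            (d.toordinal() - t0, v)
            for d, v in zip(dates, values)
            if season.onset <= d <= season.end and np.isfinite(v)
        ]
        if len(sel) < 2:
            out[year] = float("nan")
            continue
        days, vals = zip(*sel)
        rr = chemistry.demand_rate(
            days, vals, year, analyte=analyte, oxygen_max_points=oxygen_max_points
        )
        out[year] = rr.slope_per_day if rr is not None else float("nan")
    return out


def run_pipeline(
    dataset: LakeDataset, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Run the full analysis on a dataset; see the module docstring."""
    cfg = config or AnalysisConfig()
    failures: dict[str, str] = {}
    hyp = dataset.hypsography
    years = dataset.years

    epi = LayerSpec(cfg.layers.epilimnion_top, cfg.layers.epilimnion_bottom, "epilimnion")
    hypo = LayerSpec(
        cfg.layers.hypolimnion_top,
        min(cfg.layers.hypolimnion_bottom, hyp.max_depth),
        "hypolimnion",
    )

    # --- stage 1: stratification phenology -----------------------------
    seasons = None
    s_crit = float("nan")
    try:
        grid = stratification.interpolate_daily(dataset.profiles)
        daily_s = stratification.daily_stability(grid, hyp)
        s_crit = stratification.critical_stability(
            hyp,
            stratification.CriticalStabilityConfig(
                cfg.stratification.upper_temp_c,
                cfg.stratification.lower_temp_c,
                cfg.stratification.boundary_m,
            ),
        )
        seasons = stratification.stratification_seasons(grid.dates, daily_s, s_crit)
    except (ValidationError, ValueError) as err:
        failures["stratification"] = str(err)

    duration = {
        y: (seasons[y].duration_days if seasons and y in seasons else float("nan"))
        for y in years
    }

    # --- stage 2: anoxic factor ----------------------------------------
    af_annual: dict[int, float] = {}
    af_strat: dict[int, float] = {}
    try:
        for y in years:
            try:
                res = anoxia_mod.anoxic_factor(
                    dataset.profiles,
                    hyp,
                    dt.date(y, 1, 1),
                    dt.date(y, 12, 31),
                    threshold=cfg.anoxia.threshold_mg_l,
                )
                af_annual[y] = res.af_days
            except ValidationError:
                af_annual[y] = float("nan")
            season = seasons.get(y) if seasons else None
            if season is not None and season.onset is not None:
                try:
                    res = anoxia_mod.anoxic_factor(
                        dataset.profiles,
                        hyp,
                        season.onset,
                        season.end,
                        threshold=cfg.anoxia.threshold_mg_l,
                    )
                    af_strat[y] = res.af_days
                except ValidationError:
                    af_strat[y] = float("nan")
            else:
                af_strat[y] = float("nan")
    except (ValidationError, ValueError) as err:
        failures["anoxia"] = str(err)
    af = af_annual if cfg.anoxia.period == "annual" else af_strat

    # --- stage 3: seasonal concentrations and rates --------------------
    weights = chemistry.TEAWeights(cfg.tea.w_so4, cfg.tea.w_no3)
    series: dict[str, dict[int, float]] = {}
    if seasons is not None:
        try:
            d_o2, v_o2 = _profile_series(dataset, "o2_mg_l", hypo)
            d_tph, v_tph = _profile_series(dataset, "tp_ug_l", hypo)
            d_tpe, v_tpe = _profile_series(dataset, "tp_ug_l", epi)
            d_chl, v_chl = _profile_series(dataset, "chla_ug_l", epi)
            d_nh4, v_nh4 = _profile_series(dataset, "nh4_ug_l", hypo)
            d_tea, v_tea = _tea_profile_series(dataset, hypo, weights)
            series["o2_hypo"] = _seasonal_means(d_o2, v_o2, seasons)
            series["tp_hypo"] = _seasonal_means(d_tph, v_tph, seasons)
            series["tp_epi"] = _seasonal_means(d_tpe, v_tpe, seasons)
            series["chla_epi"] = _seasonal_means(d_chl, v_chl, seasons)
            series["nh4_hypo"] = _seasonal_means(d_nh4, v_nh4, seasons)
            series["tea_hypo"] = _seasonal_means(d_tea, v_tea, seasons)
            series["o2_rate"] = _rates(
                d_o2, v_o2, seasons, "o2_mg_l", cfg.rates.oxygen_max_points
            )
            series["tea_rate"] = _rates(
                d_tea, v_tea, seasons, "tea", cfg.rates.oxygen_max_points
            )
            series["nh4_rate"] = _rates(
                d_nh4, v_nh4, seasons, "nh4_ug_l", cfg.rates.oxygen_max_points
            )
        except (ValidationError, ValueError) as err:
            failures["concentrations"] = str(err)
    else:
        failures.setdefault("concentrations", "skipped: stratification failed")

    inflow_median = {}
    if dataset.inflow:
        dates_in = [r.date for r in dataset.inflow]
        vals_in = [r.tp_ug_l for r in dataset.inflow]
        for y in years:
            inflow_median[y] = chemistry.annual_median_summary(dates_in, vals_in, y).value
    series["inflow_tp"] = inflow_median

    # --- stage 4: hypolimnetic withdrawal ------------------------------
    hw_reduction: dict[int, float] = {}
    hw_outflow: dict[int, float] = {}
    effectiveness: dict[str, dict] = {}
    if dataset.withdrawal:
        try:
            table = withdrawal.hw_annual_table(dataset.withdrawal, hyp.surface_area)
            hw_reduction = {r.year: r.modeled_reduction_pct for r in table}
            hw_outflow = {r.year: r.mean_outflow_l_s for r in table}

            stock_dates, stock_vals = [], []
            for p in dataset.profiles:
                if p.has("tp_ug_l"):
                    stock_dates.append(p.date)
                    stock_vals.append(
                        hypsometry.tp_stock(p.depths, p.analyte("tp_ug_l"), hyp)
                    )
            stock_annual = {
                y: float(
                    np.mean([v for d, v in zip(stock_dates, stock_vals) if d.year == y])
                )
                for y in years
                if any(d.year == y for d in stock_dates)
            }
            d_years = sorted(set(stock_annual) & set(af))[1:]
            d_tp = [
                stock_annual[y] - stock_annual[y - 1]
                if (y - 1) in stock_annual
                else float("nan")
                for y in d_years
            ]
            d_af = [
                af[y] - af[y - 1] if (y - 1) in af else float("nan") for y in d_years
            ]
            ss = np.random.SeedSequence(cfg.stats.seed).spawn(4)
            seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
            for lag, seed_tp, seed_af in ((0, seeds[0], seeds[1]), (1, seeds[2], seeds[3])):
                try:
                    res = withdrawal.effectiveness_regressions(
                        d_years, d_tp, hw_outflow, lag=lag, b=cfg.stats.b, seed=seed_tp
                    )
                    effectiveness[f"delta_tp_stock_lag{lag}"] = {
                        "slope": res.slope,
                        "permutation_p": res.permutation_p,
                        "bootstrap_ci": res.bootstrap_ci,
                        "n": res.n,
                    }
                except ValidationError as err:
                    effectiveness[f"delta_tp_stock_lag{lag}"] = {"error": str(err)}
                try:
                    res = withdrawal.effectiveness_regressions(
                        d_years, d_af, hw_outflow, lag=lag, b=cfg.stats.b, seed=seed_af
                    )
                    effectiveness[f"delta_af_lag{lag}"] = {
                        "slope": res.slope,
                        "permutation_p": res.permutation_p,
                        "bootstrap_ci": res.bootstrap_ci,
                        "n": res.n,
                    }
                except ValidationError as err:
                    effectiveness[f"delta_af_lag{lag}"] = {"error": str(err)}
        except (ValidationError, ValueError) as err:
            failures["withdrawal"] = str(err)
    series["hw_reduction"] = hw_reduction

    # --- annual metrics table ------------------------------------------
    metrics = pd.DataFrame({"year": years})
    metrics["af_annual"] = [af_annual.get(y, float("nan")) for y in years]
    metrics["af_stratified"] = [af_strat.get(y, float("nan")) for y in years]
    metrics["duration_days"] = [duration.get(y, float("nan")) for y in years]
    for name in (
        "o2_hypo",
        "tp_hypo",
        "tp_epi",
        "chla_epi",
        "tea_hypo",
        "nh4_hypo",
        "o2_rate",
        "tea_rate",
        "nh4_rate",
        "inflow_tp",
        "hw_reduction",
    ):
        metrics[name] = [series.get(name, {}).get(y, float("nan")) for y in years]
    metrics["hw_outflow_l_s"] = [hw_outflow.get(y, float("nan")) for y in years]

    all_series = {"af": af, "duration": duration, **series}

    # --- stage 5: trend selection per series ---------------------------
    trend_results: dict[str, trends.TrendResult] = {}
    trend_rows = []
    base_ss = np.random.SeedSequence([cfg.stats.seed, 7]).spawn(len(TREND_SERIES))
    for name, ss in zip(TREND_SERIES, base_ss):
        data = all_series.get(name, {})
        x = np.array(sorted(data))
        y = np.array([data[int(v)] for v in x], dtype=float)
        ok = np.isfinite(y)
        try:
            res = trends.select_trend_model(
                x[ok],
                y[ok],
                alpha=cfg.stats.alpha,
                davies_k=cfg.stats.davies_k,
                b=cfg.stats.b,
                seed=int(ss.generate_state(1)[0] % 2**31),
            )
            trend_results[name] = res
            row = {
                "series": name,
                "model": res.kind,
                "breakpoint": res.psi,
                "breakpoint_se": res.psi_se,
                "davies_p": res.davies_p,
                "aic_linear": res.aic_linear,
                "aic_segmented": res.aic_segmented,
                "decision": res.decision,
                "n": res.n,
            }
            for key, slope in res.slopes.items():
                row[f"slope_{key}"] = slope
                ci = res.slope_cis.get(key)
                if ci:
                    row[f"ci_low_{key}"], row[f"ci_high_{key}"] = ci
                pp = res.permutation_p.get(key)
                if pp is not None:
                    row[f"perm_p_{key}"] = pp
            trend_rows.append(row)
        except (ValidationError, ValueError) as err:
            failures[f"trend:{name}"] = str(err)
    trend_table = pd.DataFrame(trend_rows)

    # --- stage 6: correlations and lag-1 feedback ----------------------
    corr_rows = []
    for a_name, b_name in CORRELATION_PAIRS:
        sa = all_series.get(a_name, {})
        sb = all_series.get(b_name, {})
        shared = sorted(set(sa) & set(sb))
        r, p = trends.pearson_cor(
            [sa[y] for y in shared], [sb[y] for y in shared]
        )
        corr_rows.append({"a": a_name, "b": b_name, "r": r, "p": p, "n": len(shared)})
    correlation_table = pd.DataFrame(corr_rows)

    lag1 = {}
    for name in ("af", "tp_hypo"):
        data = all_series.get(name, {})
        ys = sorted(y for y in data if np.isfinite(data[y]))
        try:
            r, p = trends.detrended_lag1(ys, [data[y] for y in ys])
            lag1[name] = {"r": r, "p": p, "n": len(ys)}
        except (ValidationError, ValueError) as err:
            failures[f"lag1:{name}"] = str(err)

    # --- stage 7: multiple regression + LMG ----------------------------
    lmg_out = None
    try:
        shared = [
            y
            for y in years
            if all(
                np.isfinite(all_series.get(k, {}).get(y, float("nan")))
                for k in ("af", "tp_hypo", "duration", "hw_reduction")
            )
        ]
        if len(shared) <= 5:
            raise ValidationError("too few complete years for the multiple regression")

        def _std(v):
            v = np.asarray(v, dtype=float)
            sd = np.std(v, ddof=1)
            return (v - v.mean()) / sd if sd > 0 else v - v.mean()

        resp = np.array([all_series["af"][y] for y in shared])
        preds_raw = {
            k: np.array([all_series[k][y] for y in shared])
            for k in ("tp_hypo", "duration", "hw_reduction")
        }
        imp = trends.lmg_importance(resp, {k: _std(v) for k, v in preds_raw.items()})
        imp_raw = trends.lmg_importance(resp, preds_raw)
        lmg_out = {
            "r_squared": imp.r_squared,
            "adj_r_squared": imp.adj_r_squared,
            "shares": imp.shares,
            "coefficients_std": imp.coefficients,
            "coefficients_raw": imp_raw.coefficients,
            "n": imp.n,
        }
    except (ValidationError, ValueError) as err:
        failures["lmg"] = str(err)

    provenance = {
        "package_version": _pkg_version,
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "seed": cfg.stats.seed,
        "s_crit_j_m2": s_crit,
        "n_profiles": len(dataset.profiles),
        "years": [years[0], years[-1]] if years else [],
        "density_relation": stratification.DENSITY_RELATION,
    }
    return AnalysisReport(
        annual_metrics=metrics,
        trend_table=trend_table,
        correlation_table=correlation_table,
        lag1=lag1,
        effectiveness=effectiveness,
        lmg=lmg_out,
        trend_results=trend_results,
        provenance=provenance,
        failures=failures,
    )
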