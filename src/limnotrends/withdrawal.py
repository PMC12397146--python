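"""Hypolimnetic-withdrawal accounting and effectiveness.

An Olszewski pipe siphons phosphorus-rich deep water out of the
catchment. Its long-term effect on surface phosphorus is summarised by
an empirical model relating cumulative areal TP export E (mg/m^2) to the
predicted relative reduction of epilimnetic TP:

    reduction(%) = (0.471 - 0.331 * log10(E)) * 100

Reductions are stored positive here and rendered negative ("-x% change")
in reports. The model is strictly decreasing in E, so the year-to-year
difference in reduction — the annual benefit — is never positive while
exports continue.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError, WithdrawalRecord
from . import trends

HW_MODEL_INTERCEPT = 0.471
HW_MODEL_LOG_SLOPE = 0.331


def annual_areal_tp_export(
    records: list[WithdrawalRecord], surface_area_m2: float, year: int
) -> float:
    """Areal TP export (mg per m^2) for one year.

    Each monthly record represents its calendar month: exported mass =
    TP concentration (ug/L) x outflow (L/s) x seconds in that month.
    Several records in one month are averaged before weighting.
    """
    if surface_area_m2 <= 0:
        raise ValidationError("surface area must be positive")
    in_year = [r for r in records if r.date.year == year]
    if not in_year:
        return 0.0
    mass_ug = 0.0
    for month in range(1, 13):
        in_month = [r for r in in_year if r.date.month == month]
        if not in_month:
            continue
        rate = float(np.mean([r.outflow_l_s for r in in_month]))
        tp = float(np.mean([r.tp_ug_l for r in in_month]))
        if rate < 0:
            raise ValidationError(f"negative outflow in {year}-{month:02d}")
        seconds = calendar.monthrange(year, month)[1] * 86_400
        mass_ug += tp * rate * seconds
    return mass_ug / 1000.0 / surface_area_m2  # ug -> mg, per m^2


def hw_tp_reduction(
    cumulative_export_mg_m2: float,
    intercept: float = HW_MODEL_INTERCEPT,
    log_slope: float = HW_MODEL_LOG_SLOPE,
    clamp_nonnegative: bool = False,
) -> float:
    """Predicted percent reduction of epilimnetic TP at a cumulative export.

    Evaluates (intercept - log_slope * log10(E)) * 100. The export must be
    positive (the logarithm is undefined otherwise). Optionally clamps
    negative predictions (beyond the model's zero crossing) to 0.
    """
    e = float(cumulative_export_mg_m2)
    if e <= 0:
        raise ValidationError("cumulative export must be > 0 (log10 undefined)")
    pct = (intercept - log_slope * np.log10(e)) * 100.0
    if clamp_nonnegative:
        pct = max(pct, 0.0)
    return float(pct)


def annual_benefit(years, reductions_pct) -> dict[int, float]:
    """Year-to-year first difference of the modeled reduction series.

    Returns {year: reduction[year] - reduction[year-1]} for consecutive
    year pairs only; differences across gap years are skipped.
    """
    years = list(years)
    red = list(reductions_pct)
    if len(years) < 2:
        raise ValidationError("annual benefit needs >= 2 years")
    out = {}
    for (y0, r0), (y1, r1) in zip(zip(years, red), zip(years[1:], red[1:])):
        if y1 - y0 == 1 and np.isfinite(r0) and np.isfinite(r1):
            out[y1] = float(r1 - r0)
    return out


@dataclass
class HWAnnualRecord:
    """One year of withdrawal accounting."""

    year: int
    areal_export_mg_m2: float
    cumulative_export_mg_m2: float
    modeled_reduction_pct: float  # stored positive
    mean_outflow_l_s: float


def hw_annual_table(
    records: list[WithdrawalRecord], surface_area_m2: float
) -> list[HWAnnualRecord]:
    """Per-year export, running cumulative export and modeled reduction."""
    if not records:
        return []
    years = sorted({r.date.year for r in records})
    out = []
    cumulative = 0.0
    for y in range(years[0], years[-1] + 1):
        export = annual_areal_tp_export(records, surface_area_m2, y)
        cumulative += export
        reduction = hw_tp_reduction(cumulative) if cumulative > 0 else float("nan")
        in_year = [r.outflow_l_s for r in records if r.date.year == y]
        out.append(
            HWAnnualRecord(
                year=y,
                areal_export_mg_m2=export,
                cumulative_export_mg_m2=cumulative,
                modeled_reduction_pct=reduction,
                mean_outflow_l_s=float(np.mean(in_year)) if in_year else 0.0,
            )
        )
    return out


@dataclass
class EffectivenessResult:
    """OLS slope of an annual Δ-response on HW outflow, with inference."""

    lag: int
    slope: float
    intercept: float
    permutation_p: float
    bootstrap_ci: tuple[float, float]
    n: int


def effectiveness_regressions(
    years,
    delta_response,
    outflow_by_year: dict[int, float],
    lag: int = 0,
    b: int = trends.DEFAULT_B,
    seed=None,
) -> EffectivenessResult:
    """Regress year-to-year changes (ΔTP stock or ΔAF) on mean HW outflow.

    With lag=1 the outflow of year t-1 predicts the change in year t.
    Inference is delegated to the permutation test (p) and the
    case-resampling bootstrap (CI).
    """
    if lag not in (0, 1):
        raise ValidationError("lag must be 0 or 1")
    xs, ys = [], []
    for y, dv in zip(years, delta_response):
        q = outflow_by_year.get(int(y) - lag)
        if q is not None and np.isfinite(dv) and np.isfinite(q):
            xs.append(q)
            ys.append(dv)
    x = np.asarray(xs, dtype=float)
    yv = np.asarray(ys, dtype=float)
    if x.size < 5:
        raise ValidationError("effectiveness regression needs >= 5 paired years")
    if np.ptp(x) == 0:
        raise ValidationError("outflow constant across years: slope undefined")
    xc = x - x.mean()
    slope = float(np.dot(xc, yv) / np.dot(xc, xc))
    intercept = float(yv.mean() - slope * x.mean())
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    s1, s2 = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(2)]
    p = trends.permutation_slope_test(x, yv, b=b, seed=s1)
    ci = trends.bootstrap_slope_ci(x, yv, b=b, seed=s2)
    return EffectivenessResult(
        lag=lag, slope=slope, intercept=intercept, permutation_p=p, bootstrap_ci=ci, n=x.size
    )
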