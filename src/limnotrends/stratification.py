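"""Thermal stratification phenology from monthly temperature profiles.

The workflow: interpolate each depth's monthly temperatures to daily
values with a natural cubic spline, compute daily Schmidt stability

    S = (g / A0) * ∫_0^zmax (z - z_v) * rho(T(z)) * A(z) dz      [J/m^2]

(z_v = volume-weighted mean depth of the basin), compare against a
lake-specific critical stability S_crit built from an idealised
two-layer 6 degC / 4 degC profile, and take the longest run of
consecutive days with S > S_crit in each calendar year as that year's
summer stratification season (winter / inverse stratification is thereby
excluded).

Density uses the Martin & McCutcheon fresh-water relation (maximum near
3.98 degC), the same relation common lake-analysis toolkits use.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .data_model import DepthProfile, Hypsography, ValidationError

GRAVITY = 9.81  # m/s^2

DENSITY_RELATION = "martin-mccutcheon-1999"


def water_density(temp_c) -> np.ndarray | float:
    """Fresh-water density (kg/m^3) from temperature (degC), 0..40 degC."""
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < 0.0) or np.any(t > 40.0):
        raise ValidationError("temperature outside 0..40 degC")
    rho = 1000.0 * (
        1.0 - (t + 288.9414) * (t - 3.9863) ** 2 / (508929.2 * (t + 68.12963))
    )
    return float(rho) if rho.ndim == 0 else rho


@dataclass(frozen=True)
class CriticalStabilityConfig:
    """Idealised two-layer profile defining the stratified/mixed threshold."""

    upper_temp_c: float = 6.0
    lower_temp_c: float = 4.0
    boundary_m: float = 14.0

    def __post_init__(self) -> None:
        for t in (self.upper_temp_c, self.lower_temp_c):
            if not (0.0 <= t <= 40.0):
                raise ValidationError(f"unphysical layer temperature {t} degC")
        if self.boundary_m <= 0:
            raise ValidationError("boundary depth must be positive")


@dataclass(frozen=True)
class StratificationSeason:
    """Longest stretch of consecutive stratified days in one calendar year."""

    year: int
    onset: dt.date | None
    end: dt.date | None
    duration_days: int


# ---------------------------------------------------- stability quadrature

def _mean_depth(hyp: Hypsography) -> float:
    """Volume-weighted mean depth z_v, exact for the piecewise-linear curve."""
    num = 0.0
    den = 0.0
    for a, b, aa, ab in zip(hyp.depths[:-1], hyp.depths[1:], hyp.areas[:-1], hyp.areas[1:]):
        h = b - a
        # A(z) linear on [a, b]; ∫A and ∫zA integrated exactly
        den += h * (aa + ab) / 2.0
        num += h * (a * (2 * aa + ab) + b * (aa + 2 * ab)) / 6.0
    return num / den


def _quadrature_rule(depths: np.ndarray, hyp: Hypsography, step: float):
    """Composite-Simpson nodes over [0, z_max] split at every temperature
    and hypsographic knot, with linear temperature-interpolation weights.

    Returns (z, w, i0, i1, f): T(z_j) = (1-f_j) T[i0_j] + f_j T[i1_j].
    Repeated sample depths encode a step discontinuity and produce
    zero-width segments that are skipped, keeping each side exact.
    """
    zmax = hyp.max_depth
    # segment boundaries with the temperature index active on each side
    bounds = [0.0] + [float(d) for d in depths] + [zmax]
    seg_idx = []  # (a, b, ia, ib)
    n = len(depths)
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if b - a <= 0:
            continue
        if k == 0:
            ia = ib = 0  # constant extrapolation above shallowest sample
        elif k == len(bounds) - 2:
            ia = ib = n - 1  # constant below deepest sample
        else:
            ia, ib = k - 1, k
        seg_idx.append((a, b, ia, ib))

    zs, ws, i0s, i1s, fs = [], [], [], [], []
    for a, b, ia, ib in seg_idx:
        cuts = hyp.depths[(hyp.depths > a) & (hyp.depths < b)]
        sub = np.unique(np.concatenate([[a], cuts, [b]]))
        for sa, sb in zip(sub[:-1], sub[1:]):
            m = max(1, int(np.ceil((sb - sa) / step)))
            pts = np.linspace(sa, sb, 2 * m + 1)
            h = (sb - sa) / (2 * m)
            w = np.full(2 * m + 1, 2.0)
            w[1::2] = 4.0
            w[0] = w[-1] = 1.0
            w *= h / 3.0
            frac = (pts - depths[ia]) / (depths[ib] - depths[ia]) if ib != ia else np.zeros_like(pts)
            zs.append(pts)
            ws.append(w)
            i0s.append(np.full(pts.size, ia, dtype=int))
            i1s.append(np.full(pts.size, ib, dtype=int))
            fs.append(np.clip(frac, 0.0, 1.0))
    return (
        np.concatenate(zs),
        np.concatenate(ws),
        np.concatenate(i0s),
        np.concatenate(i1s),
        np.concatenate(fs),
    )


def schmidt_stability(depths, temps, hyp: Hypsography, step: float = 0.05):
    """Schmidt stability (J/m^2) of one or many temperature profiles.

    ``temps`` may be 1-D (one profile) or 2-D with shape (n_profiles,
    n_depths), all sharing ``depths``. Repeated depths encode a step
    discontinuity (used by :func:`critical_stability`). Temperature is
    interpolated linearly between samples and held constant beyond the
    sampled range; the integral uses composite Simpson refined to
    ``step`` metres within every linear segment.
    """
    depths = np.asarray(depths, dtype=float)
    temps = np.asarray(temps, dtype=float)
    one = temps.ndim == 1
    if one:
        temps = temps[None, :]
    if temps.shape[1] != depths.size:
        raise ValidationError("temps not aligned with depths")

    # per-call missing-value policy: drop all-NaN columns only for 1-D input
    if one:
        ok = np.isfinite(temps[0])
        depths, temps = depths[ok], temps[:, ok]
    if depths.size < 2:
        raise ValidationError("Schmidt stability needs >=2 depths with temperature")
    if np.any(np.diff(depths) < 0):
        raise ValidationError("depths must be non-decreasing")
    if depths[-1] > hyp.max_depth + 1e-9:
        raise ValidationError("profile deeper than hypsography")

    z, w, i0, i1, f = _quadrature_rule(depths, hyp, step)
    zv = _mean_depth(hyp)
    coef = w * (z - zv) * hyp.area_at(z)
    t_eval = (1.0 - f) * temps[:, i0] + f * temps[:, i1]
    rho = water_density(t_eval)
    s = (GRAVITY / hyp.surface_area) * (rho @ coef)
    return float(s[0]) if one else s


def critical_stability(
    hyp: Hypsography, config: CriticalStabilityConfig | None = None, step: float = 0.05
) -> float:
    """S_crit: Schmidt stability of the idealised two-layer profile."""
    cfg = config or CriticalStabilityConfig()
    if cfg.boundary_m >= hyp.max_depth:
        raise ValidationError(
            f"two-layer boundary {cfg.boundary_m} m must lie above z_max {hyp.max_depth} m"
        )
    depths = np.array([0.0, cfg.boundary_m, cfg.boundary_m, hyp.max_depth])
    temps = np.array(
        [cfg.upper_temp_c, cfg.upper_temp_c, cfg.lower_temp_c, cfg.lower_temp_c]
    )
    return schmidt_stability(depths, temps, hyp, step=step)


# ----------------------------------------------------- daily interpolation

@dataclass(frozen=True)
class DailyTemperatureGrid:
    """Daily temperatures per depth on a contiguous date grid."""

    dates: np.ndarray  # datetime64[D]
    depths: np.ndarray
    temps: np.ndarray  # (n_days, n_depths)


def interpolate_daily(profiles: list[DepthProfile]) -> DailyTemperatureGrid:
    """Natural cubic spline of temperature over time, per depth, daily.

    Splines pass through the observations exactly. No extrapolation: the
    returned grid is restricted to dates covered by every depth. Depths
    with fewer than 4 observations fall back to linear interpolation in
    time (with a warning).
    """
    depth_sets = [tuple(p.depths.tolist()) for p in profiles if p.has("temp_c")]
    if not depth_sets:
        raise ValidationError("no profiles with temperature")
    depths = np.unique(np.concatenate([np.asarray(d) for d in depth_sets]))

    per_depth = []
    starts, ends = [], []
    obs_dates = np.array([np.datetime64(p.date, "D") for p in profiles])
    obs_t = obs_dates.astype(int).astype(float)
    for z in depths:
        ts, ys = [], []
        for p, t in zip(profiles, obs_t):
            idx = np.nonzero(np.isclose(p.depths, z))[0]
            if idx.size and np.isfinite(p.analyte("temp_c")[idx[0]]):
                ts.append(t)
                ys.append(float(p.analyte("temp_c")[idx[0]]))
        if len(ts) < 2:
            raise ValidationError(f"depth {z} m has <2 temperature observations")
        per_depth.append((np.array(ts), np.array(ys)))
        starts.append(ts[0])
        ends.append(ts[-1])

    t0, t1 = int(max(starts)), int(min(ends))
    if t1 <= t0:
        raise ValidationError("depths have no common temporal coverage")
    grid = np.arange(t0, t1 + 1)
    temps = np.empty((grid.size, depths.size))
    for j, (ts, ys) in enumerate(per_depth):
        if ts.size >= 4:
            temps[:, j] = CubicSpline(ts, ys, bc_type="natural")(grid)
        else:
            warnings.warn(
                f"depth {depths[j]} m: only {ts.size} support points, "
                "falling back to linear time interpolation",
                stacklevel=2,
            )
            temps[:, j] = np.interp(grid, ts, ys)
    dates = grid.astype("datetime64[D]")
    return DailyTemperatureGrid(dates=dates, depths=depths, temps=temps)


def daily_stability(grid: DailyTemperatureGrid, hyp: Hypsography, step: float = 0.1):
    """Daily Schmidt stability for a daily temperature grid.

    Splines can mildly overshoot between winter observations; values are
    clipped to the physical 0..40 degC range before the density relation.
    """
    temps = np.clip(grid.temps, 0.0, 40.0)
    s = schmidt_stability(grid.depths, temps, hyp, step=step)
    return np.asarray(s)


# ------------------------------------------------------------- phenology

def stratification_seasons(
    dates: np.ndarray, stability: np.ndarray, s_crit: float
) -> dict[int, StratificationSeason]:
    """Per-year longest run of consecutive days with S > S_crit.

    Strict inequality (ties count as mixed). A run that spans New Year is
    attributed to the calendar year containing its midpoint. Years where
    no day exceeds S_crit get duration 0 and null dates.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    s = np.asarray(stability, dtype=float)
    if dates.size != s.size:
        raise ValidationError("dates and stability misaligned")
    above = s > s_crit
    runs = []  # (start_idx, end_idx) inclusive
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1] and (dates[j + 1] - dates[j]).astype(int) == 1:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    years = np.arange(
        dates[0].astype("datetime64[Y]").astype(int) + 1970,
        dates[-1].astype("datetime64[Y]").astype(int) + 1971,
    )
    seasons = {
        int(y): StratificationSeason(int(y), None, None, 0) for y in years
    }
    for i, j in runs:
        mid = dates[i] + (dates[j] - dates[i]) // 2
        y = int(mid.astype("datetime64[Y]").astype(int)) + 1970
        if y not in seasons:
            continue
        dur = int((dates[j] - dates[i]).astype(int)) + 1
        if dur > seasons[y].duration_days:
            seasons[y] = StratificationSeason(
                y,
                dates[i].astype(dt.date),
                dates[j].astype(dt.date),
                dur,
            )
    return seasons


def stratification_period(
    dates: np.ndarray, stability: np.ndarray, s_crit: float, year: int
) -> StratificationSeason:
    """The stratification season of one calendar year (longest-run rule)."""
    seasons = stratification_seasons(dates, stability, s_crit)
    return seasons.get(year, StratificationSeason(year, None, None, 0))
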