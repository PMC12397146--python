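"""Synthetic 50-year lake-monitoring datasets with known ground truth.

The generator emulates the statistical structure a long-term anoxia
analysis has to recover — seasonal two-layer thermal stratification
whose Schmidt stability crosses the critical threshold twice a year,
progressive hypolimnetic oxygen depletion, an anoxic area that grows
from a parametric boundary trajectory (so the true anoxic factor is
known analytically, not via a process model), driver trends that switch
slope at a configurable breakpoint year, and an anoxia -> phosphorus ->
anoxia feedback carried by an AR(1) interannual anomaly.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import (
    DepthProfile,
    Hypsography,
    InflowRecord,
    LakeDataset,
    ValidationError,
    WithdrawalRecord,
)

DEFAULT_DEPTHS = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)

DEFAULT_NOISE = {
    "temp_c": 0.15,
    "o2_mg_l": 0.2,
    "tp_ug_l": 1.0,
    "chla_ug_l": 0.3,
    "so4_mmol_l": 0.004,
    "no3_mmol_l": 0.0015,
    "nh4_ug_l": 5.0,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic lake record.

    Trend parameters are given as the value at the breakpoint year plus a
    pre- and post-break slope (per year); setting both slopes equal gives
    a plain linear trend, setting them to zero a constant driver.
    """

    n_years: int = 50
    start_year: int = 1973
    sampling_depths: tuple = DEFAULT_DEPTHS
    profiles_per_year: int = 12
    sampling_day_of_month: int = 15
    breakpoint_year_index: int = 25

    # basin
    hypso_shape: str = "ellipsoid"  # "cone" | "ellipsoid" | "table"
    surface_area_m2: float = 134_000.0
    max_depth_m: float = 25.0
    hypso_table: tuple | None = None  # ((depth, area), ...) when shape == "table"

    # thermal seasonality (drives stratification phenology)
    hypo_temp_c: float = 4.3
    epi_o2_mg_l: float = 9.0
    thermal_amplitude_c: float = 16.0
    peak_doy: float = 200.0
    season_width_days: float = 57.0
    season_width_trend: float = 0.1875  # d/yr of width ~ 0.54 d/yr duration
    season_width_sigma: float = 3.5  # interannual width SD ~ 10 d of duration
    thermocline_depth_m: float = 11.0
    thermocline_width_m: float = 1.5

    # hypolimnetic oxygen and the anoxic window
    spring_overturn_doy: float = 45.0
    spring_o2_mg_l: float = 8.0
    o2_consumption_mg_l_d: float = 0.05
    o2_consumption_trend: float = 0.0  # per day per year
    hypo_o2_floor_mg_l: float = 1.5
    anoxia_end_doy: float = 330.0  # autumn overturn
    anoxia_ramp_days: float = 50.0
    o2_wedge_slope_mg_l_m: float = 0.6

    # anoxic factor trajectory + interannual feedback
    af_at_break_days: float = 50.0
    af_pre_slope: float = -2.0
    af_post_slope: float = 2.0
    af_sigma_days: float = 6.0  # stationary SD of the AR(1) anomaly
    phi: float = 0.5  # AR(1) persistence of the anoxia anomaly

    # phosphorus
    tp_hypo_at_break: float = 14.0
    tp_hypo_pre_slope: float = -0.5
    tp_hypo_post_slope: float = 0.23
    tp_gain_per_af_day: float = 0.15  # ug/L hypolimnetic TP per AF-day anomaly
    tp_interannual_sigma: float = 0.2
    tp_epi_at_break: float = 7.0
    tp_epi_pre_slope: float = -0.1
    tp_epi_post_slope: float = 0.0

    # other analytes
    chla_at_break: float = 2.0
    chla_pre_slope: float = -0.09
    chla_post_slope: float = 0.06
    so4_at_break: float = 0.09
    so4_slope: float = -0.0008
    no3_at_break: float = 0.015
    no3_slope: float = -0.0001
    nh4_hypo_at_break: float = 60.0
    nh4_pre_slope: float = -1.0
    nh4_post_slope: float = 1.0
    nh4_epi_ug_l: float = 20.0

    # inflow and hypolimnetic withdrawal
    inflow_tp_at_break: float = 18.0
    inflow_tp_slope: float = -0.12
    inflow_lognorm_sigma: float = 0.25
    hw_outflow_start_l_s: float = 14.0
    hw_outflow_trend: float = -0.2
    hw_outflow_sigma: float = 0.5
    hw_tp_factor: float = 1.3
    hw_tp_sigma: float = 2.0

    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise ValidationError("need >= 10 years")
        if not (0.0 <= self.phi <= 0.95):
            raise ValidationError("phi must be in [0, 0.95]")
        if max(self.sampling_depths) > self.max_depth_m:
            raise ValidationError("sampling depths exceed the basin depth")
        if not (1 <= self.profiles_per_year <= 12):
            raise ValidationError("profiles_per_year must be 1..12")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    seed: int
    breakpoint_year: int
    phi: float
    tp_gain_per_af_day: float
    af_sigma_days: float
    slopes: dict
    af_true_days: dict  # calendar year -> analytic annual anoxic factor
    af_trend_days: dict  # deterministic part only
    tp_hypo_true: dict
    duration_width_days: dict
    anoxic_window: dict  # year -> (onset doy, end doy, ramp days)

    def to_dict(self) -> dict:
        return asdict(self)


def make_hypsography(config: GeneratorConfig) -> Hypsography:
    if config.hypso_shape == "table":
        if not config.hypso_table:
            raise ValidationError("hypso_shape='table' needs hypso_table")
        arr = np.asarray(config.hypso_table, dtype=float)
        return Hypsography(arr[:, 0], arr[:, 1])
    z = np.arange(0.0, config.max_depth_m + 0.5, 1.0)
    z[-1] = config.max_depth_m
    rel = z / config.max_depth_m
    if config.hypso_shape == "cone":
        area = config.surface_area_m2 * (1.0 - rel)
    elif config.hypso_shape == "ellipsoid":
        area = config.surface_area_m2 * (1.0 - rel**2)
    else:
        raise ValidationError(f"unknown hypso shape {config.hypso_shape!r}")
    return Hypsography(z, np.maximum(area, 0.0))


def _piecewise(t: float, t_break: float, at_break: float, pre: float, post: float) -> float:
    slope = pre if t < t_break else post
    return at_break + slope * (t - t_break)


def _thermocline_shape(z: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((z - config.thermocline_depth_m) / config.thermocline_width_m))


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0):
    """Generate a complete LakeDataset plus its SyntheticTruth.

    The anoxic factor of year t is built first (trend + AR(1) anomaly),
    then realised by an anoxic-area trajectory: the anoxic fraction of
    the lake surface ramps linearly over ``anoxia_ramp_days`` to f_max
    once hypolimnetic oxygen (declining from spring overturn at the
    consumption rate) reaches the 1 mg/L threshold, and holds until
    autumn overturn, so AF_true = f_max * (window - ramp/2). The
    hypolimnetic TP of year t receives gain * (AF anomaly of year t-1),
    which induces the positive detrended lag-1 dependence of the
    internal-loading feedback.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    hyp = make_hypsography(cfg)
    tb = float(cfg.breakpoint_year_index)
    depths = np.asarray(cfg.sampling_depths, dtype=float)
    shape = _thermocline_shape(depths, cfg)

    # feasibility: the anoxic window must exist whenever AF > 0 is asked for
    rates = [
        cfg.o2_consumption_mg_l_d + cfg.o2_consumption_trend * t
        for t in range(cfg.n_years)
    ]
    if min(rates) <= 0:
        raise ValidationError("oxygen consumption rate becomes non-positive")
    worst_onset = cfg.spring_overturn_doy + (cfg.spring_o2_mg_l - 1.0) / min(rates)
    max_af_trend = max(
        _piecewise(t, tb, cfg.af_at_break_days, cfg.af_pre_slope, cfg.af_post_slope)
        for t in range(cfg.n_years)
    )
    if max_af_trend > 0 and worst_onset >= cfg.anoxia_end_doy - cfg.anoxia_ramp_days:
        raise ValidationError(
            "infeasible config: oxygen consumption too low — hypolimnetic O2 "
            f"reaches 1 mg/L only at day {worst_onset:.0f}, after the anoxic "
            f"window closes at day {cfg.anoxia_end_doy:.0f}; raise "
            "o2_consumption_mg_l_d or spring_o2_mg_l"
        )

    # interannual AR(1) anoxia anomaly (stationary SD = af_sigma_days)
    a = np.zeros(cfg.n_years)
    if cfg.af_sigma_days > 0:
        a[0] = rng.normal(0.0, cfg.af_sigma_days)
        innov_sd = cfg.af_sigma_days * np.sqrt(max(1.0 - cfg.phi**2, 0.0))
        for t in range(1, cfg.n_years):
            a[t] = cfg.phi * a[t - 1] + rng.normal(0.0, innov_sd)

    af_trend = np.array(
        [
            _piecewise(t, tb, cfg.af_at_break_days, cfg.af_pre_slope, cfg.af_post_slope)
            for t in range(cfg.n_years)
        ]
    )

    # reference anoxic window at the base (year-0) consumption rate: the AF
    # trajectory is specified at this rate, so a faster consumption schedule
    # opens the window earlier and raises the realised AF above the target
    base_onset = cfg.spring_overturn_doy + (cfg.spring_o2_mg_l - 1.0) / (
        cfg.o2_consumption_mg_l_d
    )
    eff_ref = (cfg.anoxia_end_doy - base_onset) - cfg.anoxia_ramp_days / 2.0

    years = [cfg.start_year + t for t in range(cfg.n_years)]
    af_true: dict[int, float] = {}
    tp_hypo_true: dict[int, float] = {}
    widths: dict[int, float] = {}
    windows: dict[int, tuple] = {}
    profiles: list[DepthProfile] = []
    withdrawal: list[WithdrawalRecord] = []
    inflow: list[InflowRecord] = []

    noise = {**DEFAULT_NOISE, **cfg.noise}
    months = np.linspace(1, 12, cfg.profiles_per_year).round().astype(int)

    for t, year in enumerate(years):
        width = cfg.season_width_days + cfg.season_width_trend * t
        if cfg.season_width_sigma > 0:
            width += rng.normal(0.0, cfg.season_width_sigma)
        width = max(width, 20.0)
        widths[year] = width
        r_t = rates[t]
        t_anox = cfg.spring_overturn_doy + (cfg.spring_o2_mg_l - 1.0) / r_t
        window = cfg.anoxia_end_doy - t_anox
        eff = window - cfg.anoxia_ramp_days / 2.0
        windows[year] = (float(t_anox), float(cfg.anoxia_end_doy), float(cfg.anoxia_ramp_days))

        af_target = float(np.clip(af_trend[t] + a[t], 1.0, 0.97 * max(eff_ref, 1.0)))
        f_max = af_target / eff_ref if eff_ref > 0 else 0.0
        af_true[year] = f_max * max(eff, 0.0)  # analytic AF actually realised

        prev_anom = (af_true[years[t - 1]] - af_trend[t - 1]) if t > 0 else 0.0
        h_tp = _piecewise(t, tb, cfg.tp_hypo_at_break, cfg.tp_hypo_pre_slope, cfg.tp_hypo_post_slope)
        h_tp += cfg.tp_gain_per_af_day * prev_anom
        if cfg.tp_interannual_sigma > 0:
            h_tp += rng.normal(0.0, cfg.tp_interannual_sigma)
        h_tp = max(h_tp, 1.0)
        tp_hypo_true[year] = h_tp

        e_tp = max(
            _piecewise(t, tb, cfg.tp_epi_at_break, cfg.tp_epi_pre_slope, cfg.tp_epi_post_slope), 0.5
        )
        chla = max(_piecewise(t, tb, cfg.chla_at_break, cfg.chla_pre_slope, cfg.chla_post_slope), 0.1)
        so4 = max(_piecewise(t, tb, cfg.so4_at_break, cfg.so4_slope, cfg.so4_slope), 1e-4)
        no3 = max(_piecewise(t, tb, cfg.no3_at_break, cfg.no3_slope, cfg.no3_slope), 1e-5)
        nh4_h = max(
            _piecewise(t, tb, cfg.nh4_hypo_at_break, cfg.nh4_pre_slope, cfg.nh4_post_slope), 1.0
        )
        inflow_tp = max(
            _piecewise(t, tb, cfg.inflow_tp_at_break, cfg.inflow_tp_slope, cfg.inflow_tp_slope), 1.0
        )

        for month in months:
            date = dt.date(year, int(month), cfg.sampling_day_of_month)
            doy = float(date.timetuple().tm_yday)

            # temperature: seasonal two-layer with a smooth thermocline
            delta = cfg.thermal_amplitude_c * np.exp(-(((doy - cfg.peak_doy) / width) ** 2))
            temp = cfg.hypo_temp_c + delta * shape
            temp = temp + rng.normal(0.0, noise["temp_c"], depths.size)
            temp = np.clip(temp, 0.5, 39.0)

            # oxygen: epilimnetic plateau, declining hypolimnetic background,
            # and the linear wedge pinning the 1 mg/L crossing at z_b
            if cfg.spring_overturn_doy <= doy <= cfg.anoxia_end_doy:
                bg_hypo = max(
                    cfg.hypo_o2_floor_mg_l,
                    cfg.spring_o2_mg_l - r_t * (doy - cfg.spring_overturn_doy),
                )
            else:
                bg_hypo = cfg.spring_o2_mg_l
            bg = np.where(
                depths <= 10.0,
                cfg.epi_o2_mg_l,
                np.where(
                    depths >= 14.0,
                    bg_hypo,
                    cfg.epi_o2_mg_l + (bg_hypo - cfg.epi_o2_mg_l) * (depths - 10.0) / 4.0,
                ),
            )
            frac = 0.0
            if t_anox <= doy <= cfg.anoxia_end_doy:
                frac = f_max * min((doy - t_anox) / cfg.anoxia_ramp_days, 1.0)
            if frac > 0:
                z_b = hyp.depth_at_area(frac * hyp.surface_area)
                wedge = 1.0 + cfg.o2_wedge_slope_mg_l_m * (z_b - depths)
                o2 = np.minimum(bg, np.maximum(0.15, wedge))
            else:
                o2 = bg
            o2 = np.clip(o2 + rng.normal(0.0, noise["o2_mg_l"], depths.size), 0.05, 20.0)

            # phosphorus: epilimnetic / hypolimnetic plateaus, linear 10-16 m
            tp = np.where(
                depths <= 10.0,
                e_tp,
                np.where(depths >= 16.0, h_tp, e_tp + (h_tp - e_tp) * (depths - 10.0) / 6.0),
            )
            tp = np.clip(tp + rng.normal(0.0, noise["tp_ug_l"], depths.size), 0.3, None)

            chla_z = chla * np.maximum(0.05, 1.0 - np.maximum(depths - 9.0, 0.0) / 15.0 * 0.95)
            chla_z = np.clip(chla_z + rng.normal(0.0, noise["chla_ug_l"], depths.size), 0.0, None)

            so4_z = np.clip(so4 + rng.normal(0.0, noise["so4_mmol_l"], depths.size), 0.0, None)
            no3_z = np.clip(no3 + rng.normal(0.0, noise["no3_mmol_l"], depths.size), 0.0, None)

            # ammonium accumulates through the anoxic window
            accum = 1.0
            if t_anox <= doy <= cfg.anoxia_end_doy:
                accum = 1.0 + 0.5 * (doy - t_anox) / max(cfg.anoxia_end_doy - t_anox, 1.0)
            nh4 = np.where(
                depths <= 10.0,
                cfg.nh4_epi_ug_l,
                np.where(
                    depths >= 16.0,
                    nh4_h * accum,
                    cfg.nh4_epi_ug_l
                    + (nh4_h * accum - cfg.nh4_epi_ug_l) * (depths - 10.0) / 6.0,
                ),
            )
            nh4 = np.clip(nh4 + rng.normal(0.0, noise["nh4_ug_l"], depths.size), 0.0, None)

            profiles.append(
                DepthProfile(
                    date=date,
                    depths=depths,
                    values={
                        "temp_c": temp,
                        "o2_mg_l": o2,
                        "tp_ug_l": tp,
                        "chla_ug_l": chla_z,
                        "so4_mmol_l": so4_z,
                        "no3_mmol_l": no3_z,
                        "nh4_ug_l": nh4,
                    },
                )
            )

        for month in range(1, 13):
            q = max(1.0, cfg.hw_outflow_start_l_s + cfg.hw_outflow_trend * t
                    + rng.normal(0.0, cfg.hw_outflow_sigma))
            tp_w = max(1.0, h_tp * cfg.hw_tp_factor + rng.normal(0.0, cfg.hw_tp_sigma))
            withdrawal.append(WithdrawalRecord(dt.date(year, month, 1), q, tp_w))
            inflow.append(
                InflowRecord(
                    dt.date(year, month, 8),
                    inflow_tp * float(np.exp(rng.normal(0.0, cfg.inflow_lognorm_sigma))),
                )
            )

    dataset = LakeDataset(
        profiles=profiles,
        hypsography=hyp,
        withdrawal=withdrawal,
        inflow=inflow,
        metadata={"synthetic": True, "seed": int(seed)},
    )
    truth = SyntheticTruth(
        seed=int(seed),
        breakpoint_year=cfg.start_year + cfg.breakpoint_year_index,
        phi=cfg.phi,
        tp_gain_per_af_day=cfg.tp_gain_per_af_day,
        af_sigma_days=cfg.af_sigma_days,
        slopes={
            "af_pre": cfg.af_pre_slope,
            "af_post": cfg.af_post_slope,
            "tp_hypo_pre": cfg.tp_hypo_pre_slope,
            "tp_hypo_post": cfg.tp_hypo_post_slope,
            "inflow_tp": cfg.inflow_tp_slope,
            "duration_width": cfg.season_width_trend,
        },
        af_true_days={y: float(af_true[y]) for y in years},
        af_trend_days={y: float(af_trend[t]) for t, y in enumerate(years)},
        tp_hypo_true={y: float(tp_hypo_true[y]) for y in years},
        duration_width_days={y: float(widths[y]) for y in years},
        anoxic_window={y: windows[y] for y in years},
    )
    return dataset, truth
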