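"""Anoxic boundary per oxygen profile and the annual anoxic factor.

The anoxic factor (Nürnberg) integrates the spatial extent and duration
of anoxia into one annual metric in days:

    AF = Σ_i t_i · a_i / A0

where a_i is the planar sediment-contact area at the anoxic boundary of
profile i, t_i the number of days that profile represents (midpoint rule
between consecutive sampling dates, clipped to the accounting period),
and A0 the lake surface area. Anoxia is dissolved oxygen <= 1 mg/L
(inclusive threshold).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .data_model import DepthProfile, Hypsography, ValidationError

DEFAULT_THRESHOLD_MG_L = 1.0


def anoxic_boundary(depths, oxygen_mg_l, threshold: float = DEFAULT_THRESHOLD_MG_L):
    """Shallowest depth from which the water column is anoxic to the bottom.

    Contiguous-to-bottom rule: isolated metalimnetic oxygen minima do not
    count; the boundary is the top of the deepest block of measurements
    with O2 <= threshold that reaches the bottom-most measurement,
    refined by linear interpolation of the threshold crossing between the
    last oxic and first anoxic measured depths.

    Returns None when the bottom-most measurement is oxic, 0.0 when the
    whole measured column is anoxic, NaN when all oxygen values are
    missing.
    """
    depths = np.asarray(depths, dtype=float)
    o2 = np.asarray(oxygen_mg_l, dtype=float)
    ok = np.isfinite(o2)
    if not np.any(ok):
        return float("nan")
    zs, vs = depths[ok], o2[ok]
    if zs.size < 2:
        raise ValidationError("anoxic boundary needs >=2 oxygen measurements")

    if vs[-1] > threshold:
        return None
    # walk up from the bottom through the anoxic block
    k = vs.size - 1
    while k > 0 and vs[k - 1] <= threshold:
        k -= 1
    if k == 0:
        return 0.0  # entire measured column anoxic
    z_o, v_o = zs[k - 1], vs[k - 1]  # last oxic above the block
    z_a, v_a = zs[k], vs[k]  # first anoxic of the block
    return float(z_o + (v_o - threshold) / (v_o - v_a) * (z_a - z_o))


@dataclass(frozen=True)
class AnoxicFactorResult:
    """Annual anoxic factor with its per-profile contributions."""

    year: int
    af_days: float
    threshold_mg_l: float
    period: tuple[dt.date, dt.date]
    contributions: list[dict] = field(default_factory=list)
    # each: {date, t_days, boundary_m (None if oxic), area_m2}


def _midpoint_intervals(dates: list[dt.date], start: dt.date, end: dt.date):
    """Days represented by each sampling date: midpoint rule, edges clipped
    to [start, end] (first/last intervals extend to the period edges)."""
    ords = np.array([d.toordinal() for d in dates], dtype=float)
    lo = float(start.toordinal())
    hi = float(end.toordinal()) + 1.0  # period inclusive of its last day
    if ords.size == 1:
        edges = np.array([lo, hi])
    else:
        mids = 0.5 * (ords[:-1] + ords[1:])
        edges = np.concatenate([[lo], mids, [hi]])
    edges = np.clip(edges, lo, hi)
    return np.maximum(np.diff(edges), 0.0)


def anoxic_factor(
    profiles: list[DepthProfile],
    hyp: Hypsography,
    start: dt.date,
    end: dt.date,
    threshold: float = DEFAULT_THRESHOLD_MG_L,
) -> AnoxicFactorResult:
    """Anoxic factor over an accounting period [start, end] (inclusive).

    Profiles without anoxia contribute zero area; profiles with all
    oxygen missing are excluded from the time attribution entirely.
    """
    if end < start:
        raise ValidationError(f"empty accounting period {start}..{end}")
    inside = [
        p
        for p in profiles
        if start <= p.date <= end and p.has("o2_mg_l")
    ]
    if not inside:
        raise ValidationError(
            f"no profile with oxygen inside accounting period {start}..{end}"
        )
    inside.sort(key=lambda p: p.date)
    t_days = _midpoint_intervals([p.date for p in inside], start, end)

    a0 = hyp.surface_area
    contributions = []
    total = 0.0
    for p, t in zip(inside, t_days):
        zb = anoxic_boundary(p.depths, p.analyte("o2_mg_l"), threshold)
        if zb is None or (isinstance(zb, float) and np.isnan(zb)):
            area = 0.0
            zb_out = None
        else:
            area = float(hyp.area_at(zb))
            zb_out = float(zb)
        total += t * area
        contributions.append(
            {"date": p.date, "t_days": float(t), "boundary_m": zb_out, "area_m2": area}
        )
    return AnoxicFactorResult(
        year=start.year,
        af_days=total / a0,
        threshold_mg_l=threshold,
        period=(start, end),
        contributions=contributions,
    )
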