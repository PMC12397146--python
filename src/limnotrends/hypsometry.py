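"""Volume integration over the hypsographic curve.

Layer volumes, volume-weighted layer means of a depth profile, and
whole-column mass stocks. Concentrations are interpolated linearly in
depth between sampled depths and held constant above the shallowest /
below the deepest sample; the product c(z)·A(z) is then integrated
exactly (it is piecewise quadratic, so per-segment Simpson is exact).
"""

from __future__ import annotations

import numpy as np

from .data_model import Hypsography, LayerSpec, ValidationError


def layer_volumes(hyp: Hypsography, boundaries) -> np.ndarray:
    """Volumes (m^3) of the layers delimited by consecutive boundaries."""
    b = np.asarray(boundaries, dtype=float)
    if b.size < 2 or np.any(np.diff(b) <= 0):
        raise ValidationError("boundaries must be strictly increasing, >=2 values")
    if b[0] < -1e-9 or b[-1] > hyp.max_depth + 1e-9:
        raise ValidationError(
            f"boundaries outside depth range [0, {hyp.max_depth}]"
        )
    return np.array(
        [hyp.volume_between(t, z) for t, z in zip(b[:-1], b[1:])]
    )


def _segment_knots(hyp: Hypsography, sample_depths: np.ndarray, top: float, bottom: float):
    """All breakpoints of c(z)·A(z) inside [top, bottom]."""
    inner = np.concatenate([hyp.depths, sample_depths])
    inner = inner[(inner > top) & (inner < bottom)]
    return np.unique(np.concatenate([[top], inner, [bottom]]))


def _conc_at(z, sample_depths, sample_values):
    # linear in depth, constant extrapolation beyond the sampled range
    return np.interp(z, sample_depths, sample_values)


def volume_weighted_mean(
    depths, values, hyp: Hypsography, layer: LayerSpec | tuple[float, float]
) -> float:
    """Volume-weighted mean concentration over a layer.

    mean = ∫ c(z) A(z) dz / ∫ A(z) dz over [top, bottom]. Returns NaN when
    the analyte has no non-missing values (missing propagates, never zero).
    """
    if isinstance(layer, LayerSpec):
        top, bottom = layer.top, layer.bottom
    else:
        top, bottom = layer
    if not (0.0 <= top < bottom <= hyp.max_depth + 1e-9):
        raise ValidationError(f"layer [{top}, {bottom}] outside [0, {hyp.max_depth}]")
    bottom = min(bottom, hyp.max_depth)

    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not np.any(ok):
        return float("nan")
    zs, cs = depths[ok], values[ok]

    knots = _segment_knots(hyp, zs, top, bottom)
    num = 0.0
    den = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        pts = np.array([a, 0.5 * (a + b), b])
        az = hyp.area_at(pts)
        cz = _conc_at(pts, zs, cs)
        w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])  # Simpson, exact for quadratics
        num += float(np.dot(w, cz * az))
        den += float(np.dot(w, az))
    if den <= 0:
        return float("nan")
    return num / den


def tp_stock(depths, tp_ug_l, hyp: Hypsography) -> float:
    """Whole-column phosphorus mass (g).

    Each sampled depth represents the slab between midpoints to its
    neighbours (clipped to [0, z_max]); within a slab the concentration is
    the sample value. Units: 1 µg/L = 1 mg/m^3, so stock [g] =
    Σ c_i [mg/m^3] · V_i [m^3] / 1000.
    """
    depths = np.asarray(depths, dtype=float)
    tp = np.asarray(tp_ug_l, dtype=float)
    ok = np.isfinite(tp)
    if not np.any(ok):
        return float("nan")
    zs, cs = depths[ok], tp[ok]
    if zs.size == 1:
        return cs[0] * hyp.total_volume / 1000.0
    mids = 0.5 * (zs[:-1] + zs[1:])
    edges = np.concatenate([[0.0], mids, [hyp.max_depth]])
    edges = np.clip(edges, 0.0, hyp.max_depth)
    mass_mg = 0.0
    for c, t, b in zip(cs, edges[:-1], edges[1:]):
        if b > t:
            mass_mg += c * hyp.volume_between(t, b)
    return mass_mg / 1000.0
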