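"""Trend statistics: segmented (breakpoint) regression, Davies test,
model selection, permutation slope tests, bootstrap CIs, detrended lag-1
correlation and LMG variance partitioning.

The segmented fit follows Muggeo's iterative linearisation: augment the
linear model with U = (x - psi)_+ and V = -1[x > psi], refit, and update
psi <- psi + gamma_hat / betaU_hat until the V coefficient gamma
vanishes. The Davies test bounds the p-value of the best slope change
over a grid of candidate breakpoints. Slope inference is non-parametric:
a permutation test (reshuffling y) for the p-value and a case-resampling
percentile bootstrap for the confidence interval — two distinct
procedures, reported separately.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import ValidationError

DEFAULT_B = 10_000
DEFAULT_ALPHA = 0.05
DEFAULT_DAVIES_K = 10


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC with Gaussian likelihood; k counts all parameters incl. sigma."""
    sigma2 = max(rss / n, 1e-300)
    return n * math.log(2 * math.pi * sigma2) + n + 2 * k


# ------------------------------------------------------------- segmented

@dataclass
class SegmentedFit:
    """A converged piecewise-linear fit with one breakpoint."""

    psi: float
    left_slope: float
    right_slope: float
    intercept: float
    left_slope_se: float
    right_slope_se: float
    psi_se: float
    residuals: np.ndarray
    rss: float
    aic: float
    converged: bool
    boundary: bool  # psi driven to the admissible edge -> no interior break
    n_iter: int


def fit_segmented(
    x,
    y,
    psi0: float | None = None,
    max_iter: int = 50,
    tol: float | None = None,
) -> SegmentedFit:
    """Muggeo iterative linearisation for one breakpoint.

    psi is constrained strictly inside the x-range, excluding the outer
    two points on each side. Non-convergence or a boundary psi is flagged
    (callers fall back to the linear model).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 7:
        raise ValidationError("segmented fit needs n >= 7")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant")
    xs = np.sort(x)
    lo, hi = xs[2], xs[-3]
    if hi <= lo:
        raise ValidationError("too few distinct x values for an interior breakpoint")
    sd_y = float(np.std(y))
    if sd_y == 0.0:
        raise ValidationError("y is constant: breakpoint unidentifiable")
    tol = tol if tol is not None else 1e-8 * sd_y
    psi = float(psi0) if psi0 is not None else float(np.median(x))
    psi = float(np.clip(psi, lo, hi))

    def _rss3(p: float) -> float:
        u = np.maximum(x - p, 0.0)
        design = np.column_stack([np.ones(n), x, u])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r)

    converged = False
    boundary = False
    damping = 1.0
    prev_step = 0.0
    hit_edge = 0
    best_psi, best_rss = psi, _rss3(psi)
    for it in range(1, max_iter + 1):
        u = np.maximum(x - psi, 0.0)
        v = -(x > psi).astype(float)
        design = np.column_stack([np.ones(n), x, u, v])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < 4:
            boundary = True
            break
        gamma = beta[3]
        b_u = beta[2]
        if abs(b_u) < 1e-12 * max(sd_y, 1e-12):
            boundary = True  # slope change vanishing: breakpoint unidentifiable
            break
        if abs(gamma) < tol:
            converged = True
            break
        step = damping * gamma / b_u
        if step * prev_step < 0:  # oscillation across a data point: damp
            damping *= 0.6
            step = damping * gamma / b_u
        prev_step = step
        new_psi = psi + step
        if new_psi <= lo or new_psi >= hi:
            hit_edge += 1
            if hit_edge >= 3:
                boundary = True
                psi = float(np.clip(new_psi, lo, hi))
                break
        psi = float(np.clip(new_psi, lo, hi))
        rss_here = _rss3(psi)
        if rss_here < best_rss:
            best_rss, best_psi = rss_here, psi
    n_iter = it

    if not boundary:
        # polish: the working-model iteration can hop between the kinks of
        # RSS(psi); a bounded scalar search around the best iterate settles
        # on the local optimum the same way a grid refinement would
        from scipy.optimize import minimize_scalar

        xs_u = np.unique(xs)
        span = xs_u[-1] - xs_u[0]
        dx = max(np.median(np.diff(xs_u)), 1e-9 * span)
        blo = max(lo, best_psi - 2 * dx)
        bhi = min(hi, best_psi + 2 * dx)
        if bhi > blo:
            opt = minimize_scalar(_rss3, bounds=(blo, bhi), method="bounded",
                                  options={"xatol": 1e-8 * span})
            if opt.fun <= best_rss + 1e-12:
                best_psi = float(opt.x)
        psi = best_psi
        if lo + 1e-9 < psi < hi - 1e-9:
            converged = True
        else:
            boundary = True

    # covariance of the working model at the final psi (for the SEs)
    psi_se = float("nan")
    u = np.maximum(x - psi, 0.0)
    v = -(x > psi).astype(float)
    design4 = np.column_stack([np.ones(n), x, u, v])
    beta4, _, rank4, _ = np.linalg.lstsq(design4, y, rcond=None)
    resid4 = y - design4 @ beta4
    rss4 = float(resid4 @ resid4)
    dof4 = n - 4
    if rank4 == 4 and dof4 > 0 and rss4 > 0 and abs(beta4[2]) > 0:
        cov = (rss4 / dof4) * np.linalg.inv(design4.T @ design4)
        g, b_u = beta4[3], beta4[2]
        # delta method on the ratio gamma / betaU
        var = (
            cov[3, 3] / b_u**2
            + (g**2 / b_u**4) * cov[2, 2]
            - 2 * (g / b_u**3) * cov[3, 2]
        )
        psi_se = float(np.sqrt(max(var, 0.0)))

    # final refit without the V working term
    u = np.maximum(x - psi, 0.0)
    design = np.column_stack([np.ones(n), x, u])
    beta3, _, rank3, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta3
    rss = float(resid @ resid)
    dof = n - 3
    if rank3 == 3 and dof > 0 and rss > 0:
        sigma2 = rss / dof
        cov3 = sigma2 * np.linalg.inv(design.T @ design)
        se_b1 = float(np.sqrt(cov3[1, 1]))
        se_right = float(np.sqrt(cov3[1, 1] + cov3[2, 2] + 2 * cov3[1, 2]))
    else:
        se_b1 = se_right = 0.0
    aic = _gaussian_aic(rss, n, k=5)  # intercept, 2 slopes, psi, sigma
    return SegmentedFit(
        psi=psi,
        left_slope=float(beta3[1]),
        right_slope=float(beta3[1] + beta3[2]),
        intercept=float(beta3[0]),
        left_slope_se=se_b1,
        right_slope_se=se_right,
        psi_se=psi_se,
        residuals=resid,
        rss=rss,
        aic=aic,
        converged=converged and not boundary,
        boundary=boundary,
        n_iter=n_iter,
    )


# ----------------------------------------------------------- Davies test

def davies_test(x, y, k: int = DEFAULT_DAVIES_K) -> float:
    """Upper bound for the p-value of a slope change at an unknown break.

    For each of k candidate breakpoints (interior 10%..90% quantiles of
    x) the t statistic for adding (x - psi)_+ to the linear model is
    computed; Davies' bound for the maximum of the correlated statistics
    gives p <= 2*[P(t_df > M) + V * f_df(M) / 2], with V the total
    variation of the t path over candidates and f_df the t density (the
    t-process version of the bound; the Gaussian-density form is too
    liberal at the small sample sizes of annual series).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError("Davies test needs n >= 10")
    if k < 2:
        raise ValidationError("Davies test needs >= 2 evaluation points")
    if np.ptp(y) == 0:
        return 1.0
    psis = np.unique(np.quantile(x, np.linspace(0.1, 0.9, k)))
    if psis.size < 2:
        return 1.0

    tvals = []
    for psi in psis:
        u = np.maximum(x - psi, 0.0)
        design = np.column_stack([np.ones(n), x, u])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        rss = float(resid @ resid)
        dof = n - 3
        if rank < 3 or rss <= 0 or dof <= 0:
            tvals.append(0.0)
            continue
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = math.sqrt(max(cov[2, 2], 0.0))
        tvals.append(beta[2] / se if se > 0 else 0.0)
    tvals = np.asarray(tvals)
    m = float(np.max(np.abs(tvals)))
    if m == 0.0:
        return 1.0
    vtot = float(np.sum(np.abs(np.diff(tvals))))
    df = n - 3
    p_one = stats.t.sf(m, df) + vtot * stats.t.pdf(m, df) / 2.0
    return float(min(max(2.0 * p_one, np.nextafter(0, 1)), 1.0))


# ------------------------------------------------- permutation / bootstrap

def permutation_slope_test(
    x, y, b: int = DEFAULT_B, seed=None, alternative: str = "two-sided"
) -> float:
    """Permutation p-value for the OLS slope of y on x.

    y is reshuffled against x; two-sided p = (1 + #{|b*| >= |b_obs|}) /
    (B + 1). When n! <= B all permutations are enumerated and the p-value
    is exact (#/n!). Zero-variance y gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValidationError("permutation test needs n >= 5")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant")
    if np.ptp(y) == 0:
        return 1.0
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    b_obs = abs(float(np.dot(xc, y)) / denom)

    if math.factorial(n) <= b:
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            slope = abs(float(np.dot(xc, perm)) / denom)
            count += slope >= b_obs - 1e-12
            total += 1
        return count / total

    rng = np.random.default_rng(seed)
    yy = np.tile(y, (b, 1))
    perms = rng.permuted(yy, axis=1)
    slopes = np.abs(perms @ xc / denom)
    exceed = int(np.sum(slopes >= b_obs - 1e-12))
    return (1 + exceed) / (b + 1)


def bootstrap_slope_ci(
    x, y, b: int = DEFAULT_B, seed=None, level: float = 0.95
) -> tuple[float, float]:
    """Case-resampling percentile bootstrap CI for the OLS slope.

    Resamples (x, y) pairs with replacement; degenerate resamples
    (constant x) are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValidationError("bootstrap CI needs n >= 5")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    xb = x[idx]
    yb = y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = np.sum((xb - xm) ** 2, axis=1)
    sxy = np.sum((xb - xm) * (yb - ym), axis=1)
    ok = sxx > 0
    slopes = sxy[ok] / sxx[ok]
    if slopes.size == 0:
        raise ValidationError("all bootstrap resamples degenerate")
    a = (1.0 - level) / 2.0
    lo, hi = np.percentile(slopes, [100 * a, 100 * (1 - a)])
    return float(lo), float(hi)


# -------------------------------------------------------- model selection

@dataclass
class TrendResult:
    """Outcome of the linear-vs-segmented decision for one annual series."""

    kind: str  # "linear" | "segmented"
    psi: float | None
    psi_se: float | None
    slopes: dict[str, float]  # {"slope": } or {"left": , "right": }
    slope_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    permutation_p: dict[str, float] = field(default_factory=dict)
    davies_p: float = float("nan")
    aic_linear: float = float("nan")
    aic_segmented: float = float("nan")
    decision: str = ""
    n: int = 0


def select_trend_model(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    davies_k: int = DEFAULT_DAVIES_K,
    b: int = DEFAULT_B,
    seed=None,
) -> TrendResult:
    """Linear vs one-breakpoint model, by the Davies-then-AIC rule.

    Rule order: (1) Davies p < alpha -> segmented; (2) else
    AIC(segmented) < AIC(linear) -> segmented; (3) else linear. Slope
    inference: permutation p per slope, case-bootstrap percentile CI.
    For the segmented model each segment's points are refit separately
    for its permutation/bootstrap inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 7:
        raise ValidationError("trend selection needs n >= 7")

    if np.ptp(y) == 0:
        return TrendResult(
            kind="linear",
            psi=None,
            psi_se=None,
            slopes={"slope": 0.0},
            permutation_p={"slope": 1.0},
            davies_p=1.0,
            decision="constant response -> linear",
            n=n,
        )

    # linear fit
    slope = _ols_slope(x, y)
    resid = y - (y.mean() + slope * (x - x.mean()))
    aic_lin = _gaussian_aic(float(resid @ resid), n, k=3)

    seg = None
    davies_p = 1.0
    aic_seg = float("inf")
    try:
        davies_p = davies_test(x, y, k=davies_k)
        seg = fit_segmented(x, y)
        if seg.converged:
            aic_seg = seg.aic
    except ValidationError:
        seg = None

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seeds = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(4)]

    use_segmented = seg is not None and seg.converged
    if use_segmented and davies_p < alpha:
        decision = f"davies p={davies_p:.4g} < {alpha} -> segmented"
    elif use_segmented and aic_seg < aic_lin:
        decision = (
            f"davies p={davies_p:.4g} >= {alpha}; "
            f"AIC segmented {aic_seg:.2f} < linear {aic_lin:.2f} -> segmented"
        )
    else:
        use_segmented = False
        why = "no admissible breakpoint" if seg is None or not seg.converged else (
            f"davies p={davies_p:.4g} >= {alpha}; AIC favours linear "
            f"({aic_lin:.2f} <= {aic_seg:.2f})"
        )
        decision = why + " -> linear"

    if use_segmented:
        left = x <= seg.psi
        right = ~left
        out = TrendResult(
            kind="segmented",
            psi=seg.psi,
            psi_se=seg.psi_se,
            slopes={"left": seg.left_slope, "right": seg.right_slope},
            davies_p=davies_p,
            aic_linear=aic_lin,
            aic_segmented=aic_seg,
            decision=decision,
            n=n,
        )
        for name, mask, sd in (("left", left, seeds[0:2]), ("right", right, seeds[2:4])):
            xs, ys = x[mask], y[mask]
            if xs.size >= 5 and np.ptp(xs) > 0:
                out.permutation_p[name] = permutation_slope_test(xs, ys, b=b, seed=sd[0])
                out.slope_cis[name] = bootstrap_slope_ci(xs, ys, b=b, seed=sd[1])
        return out

    out = TrendResult(
        kind="linear",
        psi=None,
        psi_se=None,
        slopes={"slope": slope},
        davies_p=davies_p,
        aic_linear=aic_lin,
        aic_segmented=aic_seg if np.isfinite(aic_seg) else float("nan"),
        decision=decision,
        n=n,
    )
    out.permutation_p["slope"] = permutation_slope_test(x, y, b=b, seed=seeds[0])
    out.slope_cis["slope"] = bootstrap_slope_ci(x, y, b=b, seed=seeds[1])
    return out


# ------------------------------------------------------------ correlation

def pearson_cor(a, b) -> tuple[float, float]:
    """Pearson r with t-test p; pairwise deletion of missing values.

    Returns (nan, nan) for fewer than 3 complete pairs or zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    aa, bb = a[ok], b[ok]
    if np.ptp(aa) == 0 or np.ptp(bb) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(aa, bb)
    return float(r), float(p)


def detrended_lag1(years, values, min_years: int = 10) -> tuple[float, float]:
    """Lag-1 Pearson correlation of detrended annual residuals.

    Removes the linear-in-time trend, then correlates residual_t with
    residual_{t+1}; pairs spanning a year gap are dropped. A perfectly
    linear series (all-zero residuals) gives (nan, nan).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    years, values = years[ok], values[ok]
    if years.size < min_years:
        raise ValidationError(f"detrended lag-1 needs >= {min_years} years")
    slope = _ols_slope(years, values)
    resid = values - (values.mean() + slope * (years - years.mean()))
    if np.std(resid) < 1e-12 * max(np.std(values), 1e-12):
        return float("nan"), float("nan")
    consecutive = np.diff(years) == 1
    a = resid[:-1][consecutive]
    b = resid[1:][consecutive]
    return pearson_cor(a, b)


# ---------------------------------------------------------- LMG importance

@dataclass
class ImportanceResult:
    """Decomposition of a multiple regression's R^2 into predictor shares."""

    r_squared: float
    adj_r_squared: float
    shares: dict[str, float]  # LMG share of R^2 per predictor
    coefficients: dict[str, tuple[float, float]]  # name -> (beta, se)
    n: int


def _subset_r2(xmat: np.ndarray, y: np.ndarray, cols: tuple[int, ...], cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    n = y.size
    if not cols:
        cache[cols] = 0.0
        return 0.0
    design = np.column_stack([np.ones(n), xmat[:, list(cols)]])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValidationError("rank-deficient design in R^2 subset")
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    cache[cols] = r2
    return r2


def lmg_importance(y, predictors: dict[str, np.ndarray]) -> ImportanceResult:
    """Lindeman-Merenda-Gold relative importance by exhaustive orderings.

    For every ordering of the predictors, record the increase in R^2 when
    each predictor enters; the LMG share is the average over all
    orderings. Shares are non-negative and sum to the full model's R^2.
    Limited to <= 8 predictors (exhaustive enumeration).
    """
    names = list(predictors)
    p = len(names)
    if p == 0 or p > 8:
        raise ValidationError("LMG needs 1..8 predictors")
    y = np.asarray(y, dtype=float)
    xmat = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    ok = np.isfinite(y) & np.all(np.isfinite(xmat), axis=1)
    y, xmat = y[ok], xmat[ok]
    n = y.size
    if n <= p + 2:
        raise ValidationError("LMG needs n > predictors + 2")

    cache: dict = {}
    shares = {k: 0.0 for k in names}
    orders = list(itertools.permutations(range(p)))
    for order in orders:
        before: tuple[int, ...] = ()
        for j in order:
            r2_with = _subset_r2(xmat, y, tuple(sorted(before + (j,))), cache)
            r2_without = _subset_r2(xmat, y, before, cache)
            shares[names[j]] += r2_with - r2_without
            before = tuple(sorted(before + (j,)))
    for k in names:
        shares[k] /= len(orders)

    r2 = _subset_r2(xmat, y, tuple(range(p)), cache)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    design = np.column_stack([np.ones(n), xmat])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - p - 1
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    coefs = {
        name: (float(beta[j + 1]), float(np.sqrt(cov[j + 1, j + 1])))
        for j, name in enumerate(names)
    }
    coefs["intercept"] = (float(beta[0]), float(np.sqrt(cov[0, 0])))
    return ImportanceResult(
        r_squared=r2, adj_r_squared=adj, shares=shares, coefficients=coefs, n=n
    )
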