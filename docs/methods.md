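# Methods

This note documents the models, numerical choices and open design
decisions behind `limnotrends`. The package analyses ~50-year monthly
monitoring records of a small stratifying lake: depth profiles of
temperature, dissolved oxygen, total phosphorus (TP), chlorophyll-a,
sulfate, nitrate and ammonium, together with a hypsographic curve and
records of hypolimnetic withdrawal (HW) and inflow TP.

## Hypsographic integration

All volume integrals run over the tabulated depth→area curve A(z),
linearly interpolated between rows. Volumes are exact trapezoids of the
piecewise-linear curve. Volume-weighted layer means integrate
c(z)·A(z) continuously, with the analyte interpolated linearly between
sampled depths and held constant beyond the sampled range; because the
integrand is piecewise quadratic, per-segment Simpson evaluation is
exact, and a layer mean is invariant to refining the hypsographic grid.
Integrating continuously (rather than assigning whole sample depths to
layers) removes any sensitivity to whether a sampling depth "belongs"
to a layer. Whole-column TP stocks instead follow the conventional
midpoint-slab accounting (each sample represents the slab between the
midpoints to its neighbours) with 1 µg/L = 1 mg/m³.

## Stratification phenology

Monthly temperatures are interpolated per depth to daily values with a
natural cubic spline over the full record (no extrapolation beyond the
first/last observation; depths with fewer than four support points fall
back to linear interpolation with a warning). Daily Schmidt stability

    S = (g / A0) ∫ (z − z_v) ρ(T(z)) A(z) dz        [J/m²]

uses the Martin–McCutcheon fresh-water density relation (maximum near
3.98 °C; the relation's name is recorded in the report provenance so the
choice is auditable). The integral splits at every temperature and
hypsography knot and applies composite Simpson refined to 0.05 m (0.1 m
for the vectorised daily series); both are far inside the 1e-6 relative
agreement the tests require against an independent 1-cm quadrature
oracle. Repeated depths encode a step discontinuity, which lets the
critical stability S_crit be computed *by the same routine* applied to
an idealised two-layer profile — 6 °C above the configured boundary
(default 14 m), 4 °C below — so the identity
`critical_stability ≡ schmidt_stability(two-layer profile)` holds
exactly. A day is stratified when S > S_crit (strict; a tie counts as
mixed). The summer season of a year is the longest run of consecutive
stratified days; a run spanning New Year is attributed to the year
containing its midpoint. This operationalises the exclusion of the more
irregular winter stratification without an explicit ice model.

## Anoxic factor

Anoxia is dissolved oxygen ≤ 1 mg/L (inclusive). Per profile, the
anoxic boundary is the top of the deepest contiguous block of anoxic
measurements that reaches the bottom-most measurement, refined by linear
interpolation of the threshold crossing; isolated metalimnetic oxygen
minima therefore never define the boundary (the metric targets
sediment-contact anoxia). The annual anoxic factor is

    AF = Σ t_i · a_i / A0        [days]

with a_i the planar area at profile i's boundary and t_i the days the
profile represents (midpoint rule between sampling dates, first/last
interval clipped to the accounting period). AF is computed both for the
calendar year and for the stratified season; the `anoxia.period` config
key selects which one drives the downstream trend analysis (annual by
default). AF is monotone in the threshold, invariant to scaling the
hypsography, and bounded by the period length.

## Chemistry

Terminal-electron-acceptor (TEA) concentrations weight sulfate and
nitrate (mmol/L) by their energy yield relative to aerobic respiration:
w_SO4 = 0.197 and w_NO3 = 0.84 by default. The printed nitrate yields
(−28.4 and −19.6 kJ/mol against −29.98 for oxygen) actually average to
≈0.80, not 0.84; the package defaults to the published rounded constant
and exposes the derivation (`TEAWeights.from_energy_yields`) rather than
silently "fixing" the discrepancy. Seasonal summaries are mean ± SE over
the stratified window (median ± IQR, linear-interpolation quantile rule,
for inflow TP). Demand/accumulation rates are OLS slopes of the
volume-weighted concentration against days since stratification onset;
for oxygen only the first four non-missing in-season measurements enter
(later values are already depleted and flatten the fit), for TEA and
ammonium all in-season points are used. N:P is molar, with
N = nitrate-N + ammonium-N (NH4 molar mass 18.04 g/mol, P 30.974 g/mol).

## Hypolimnetic withdrawal

Each monthly withdrawal record represents its calendar month
(days-in-month weighting). Annual areal TP export is Σ concentration ×
outflow volume / A0, in mg/m²; the cumulative export E feeds the
empirical effectiveness model

    reduction(%) = (0.471 − 0.331 · log10 E) · 100

which is strictly decreasing, so the year-to-year "annual benefit" is
never positive while exports continue. E is in mg/m², the source
model's convention; the units are centralised in one config point
because the formula is unit-sensitive. Reductions are stored positive
and rendered negative in reports. Year-to-year changes in TP stock and
AF are regressed on mean annual outflow (lags 0 and 1) with the same
non-parametric inference as every other slope.

## Trend statistics

*Segmented regression.* One-breakpoint fits use Muggeo's iterative
linearisation (working terms U = (x−ψ)+ and V = −1[x>ψ], update
ψ ← ψ + γ̂/β̂_U). The iteration can oscillate between the kinks of
RSS(ψ); steps are damped (×0.6 on each sign flip), the best-RSS iterate
is tracked, and a bounded scalar search around it settles on the local
optimum — equivalent to the grid refinement practitioners bolt onto the
working-model iteration. ψ is constrained strictly inside the x-range
excluding the outer two points per side; a vanishing slope change or a
ψ driven to that boundary flags the breakpoint as non-identifiable and
the caller falls back to the linear model. SE(ψ) comes from the delta
method on γ/β_U; AIC uses the Gaussian likelihood with k = 5 (two
slopes, intercept, ψ, σ) against k = 3 for the line.

*Davies test.* For 10 candidate breakpoints at the interior 10–90%
quantiles, the t statistic for adding (x−ψ)+ is computed; the p-value
bound for the maximum is `2·[P(t_df > M) + V·f_df(M)/2]` with V the
total variation of the t path and f_df the t density. The t-process
form matters: the Gaussian-density correction is measurably liberal at
annual-series sample sizes (size ≈0.075 at α = 0.05 versus ≈0.045 for
the t form).

*Model choice.* In order: Davies p < 0.05 → segmented; else
AIC(segmented) < AIC(linear) → segmented; else linear, with the firing
rule recorded in a decision trace. Under a pure-line null this cascade
retains an irreducible ≈12% breakpoint-selection rate (≈5% Davies +
≈7% AIC pickups) — a known cost of the AIC fallback, worth keeping in
mind when reading single-series decisions.

*Slope inference.* The permutation test (reshuffle y, two-sided
p = (1+#{|b*| ≥ |b|})/(B+1), exact enumeration when n! ≤ B) and the
case-resampling percentile bootstrap CI are deliberately distinct
procedures: permutations test the no-association null but cannot give a
CI, resampling gives the CI. Both default to B = 10 000 and are
bit-reproducible given a seed. Percentile intervals under-cover by
roughly one point at n = 100 (≈94% for a nominal 95%), as expected for
this CI type.

*Feedback.* Interannual persistence is the lag-1 Pearson correlation of
residuals from a linear-in-time fit, with pairs spanning year gaps
dropped. Note that linear detrending of a series whose true trend is
segmented leaves the V-shape in the residuals and inflates the lag-1
correlation; the synthetic feedback-recovery experiments therefore run
with flat trends so the AR(1) component is measured in isolation.

*LMG importance.* The multiple regression of AF on hypolimnetic TP,
stratification duration and modeled HW reduction is decomposed by
exhaustive enumeration of predictor orderings (≤8 predictors); shares
are non-negative and sum to R² by construction, and are verified in
tests against an independent subset-weighted (Shapley) enumeration.
Predictors are standardised before the decomposition (shares are
scale-dependent otherwise); raw-scale coefficients are reported
alongside.

## Synthetic lakes

The generator's goal is exact, analytically known ground truth, not
biogeochemical realism. Defaults describe a 50-year record, nine
sampling depths (0–24 m every 3 m), 12 profiles/year, a 134 000 m²
basin with a convex area curve to 25 m, and a single breakpoint at year
index 25 shared by all segmented drivers.

* **Thermal seasonality**: a Gaussian seasonal pulse (amplitude 16 °C,
  peak day 200) applied above a logistic thermocline (11 m, width
  1.5 m) over a 4.3 °C hypolimnion. The pulse width (57 d + 0.1875 d/yr
  + N(0, 3.5 d)) translates into a stratification duration of ≈165 d
  with a ≈0.54 d/yr trend and ≈10 d interannual scatter — the scatter is
  set so that the duration trend's uncertainty is of the order long
  records actually show, and it is what keeps near-noiseless series from
  producing spurious breakpoint detections.
* **Oxygen and AF**: hypolimnetic oxygen declines from spring overturn
  (day 45, 8 mg/L) at the configured consumption rate (0.05 mg/L/d);
  the anoxic window opens when it reaches 1 mg/L and closes at autumn
  overturn (day 330). Within the window the anoxic area fraction ramps
  linearly (50 d) to f_max and holds, so the true AF is the closed-form
  f_max·(window − ramp/2). f_max is set from a target AF trajectory
  evaluated at the *base* consumption rate, so raising the consumption
  schedule opens the window earlier and strictly raises realised AF.
  An oxygen "wedge" of slope 0.6 mg/L/m pins the 1 mg/L crossing at the
  intended boundary depth, so the profile-based AF estimator recovers
  the analytic truth to within midpoint-rule discretisation (a few days
  at monthly sampling).
* **Trajectories**: AF follows −3.0/+3.5 d/yr around 50 d at the break;
  hypolimnetic TP follows −0.5/+0.23 µg/L/yr around 14 µg/L (slopes of
  the magnitude re-eutrophication records report); inflow TP, sulfate
  and nitrate decline linearly; ammonium switches from decline to rise.
* **Feedback**: the interannual AF anomaly is AR(1) with persistence
  φ = 0.5 and stationary SD 6 d; hypolimnetic TP in year t receives
  gain × (AF anomaly of year t−1) with gain 0.15 µg/L per AF-day, which
  induces the positive detrended lag-1 dependence of internal loading.
  These defaults were chosen so the configured breakpoints are
  recoverable within ±3 years from a single 50-year realisation — a
  property the synthetic-truth contract requires — while keeping the
  lag-1 correlation in the 0.3–0.5 range reported for real records.
* **Noise**: independent Gaussian per measurement (temperature 0.15 °C,
  oxygen 0.2 mg/L, TP 1 µg/L, …), truncated at physical bounds.

What the generator does *not* emulate: within-season TP dynamics,
metalimnetic oxygen minima, ice phenology and inverse stratification,
sediment flux mechanics, meromixis, and measurement-method changes over
decades. Passing the recovery tests therefore demonstrates that the
pipeline's estimators are consistent with their own definitions under
realistic noise — not that the estimators are robust to every artefact
of real monitoring data.

## Degenerate inputs and numerical conventions

Missing values propagate as NaN and never silently become zeros; a
layer with no data yields a missing mean, an all-missing oxygen profile
contributes nothing to AF's time base. Constant series short-circuit to
the linear model (p = 1) rather than exercising the breakpoint
machinery on round-off noise. CSVs are written with `%.17g` and read
with round-trip float parsing so write→read is exact. Every stochastic
routine takes an explicit seed, and the pipeline derives per-stage seeds
from one master seed via `SeedSequence`, so a report is reproducible
bit-for-bit from its provenance block.

## Problem sizes used in verification

The calibration experiments use 500 null simulations for permutation
uniformity (B = 199), 1000 for the Davies size, 500 for bootstrap
coverage (n = 100, B = 999), 200 segmented-recovery simulations and 200
synthetic-lake replicates for feedback recovery — sizes at which the
Monte-Carlo error of each rate is comfortably below the width of the
band being checked.

## Known limitations

* A lake-specific critical stability is only as good as that lake's
  measured bathymetry; the packaged checks use toy basins with exact
  quadrature oracles instead of any particular survey.
* No autocorrelation-robust trend errors: permutation p-values assume
  exchangeability, which positive lag-1 persistence violates. This
  keeps the established field practice; the detrended lag-1 diagnostic
  is the tool for judging how much it matters.
* No multiple-testing correction across the many series tested.
* The HW effectiveness model is an empirical regression imported from
  the restoration literature; its intercept/slope are config, not fit.
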