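# limnotrends

Long-term lake deoxygenation analysis: from monthly depth profiles and a
hypsographic curve to stratification phenology, anoxic factors,
energy-weighted electron-acceptor budgets, hypolimnetic-withdrawal
effectiveness, and a breakpoint/permutation/bootstrap trend workflow
with LMG variance partitioning.

## Who this is for

Limnologists and ecosystem modellers with multi-decade monitoring
records of small stratifying lakes — the kind of record where the
questions are: when does the water column stratify and for how long,
how much sediment area sits under anoxic water each year, is the lake
recovering or re-eutrophying, did the trend change direction and when,
and which mechanism (internal phosphorus loading, longer stratification,
waning withdrawal effectiveness) carries the signal.

## The quantities at the core

* **Schmidt stability** `S = (g/A₀) ∫ (z − z_v) ρ(T(z)) A(z) dz` (J/m²),
  computed daily from spline-interpolated monthly profiles. A day is
  stratified when `S > S_crit`, where `S_crit` is the stability of an
  idealised two-layer 6 °C / 4 °C profile over the same basin; the
  longest run of stratified days is the year's summer season.
* **Anoxic factor** `AF = Σ tᵢ·aᵢ / A₀` (days/yr): duration-weighted
  anoxic sediment area, with anoxia defined as O₂ ≤ 1 mg/L and the
  boundary required to be contiguous to the bottom.
* **Weighted TEA concentration** `0.197·[SO₄²⁻] + 0.84·[NO₃⁻]` (mmol
  O₂-equivalents/L): electron acceptors scaled by energy yield relative
  to aerobic respiration.
* **HW effectiveness** `reduction(%) = (0.471 − 0.331·log₁₀ E)·100` for
  cumulative areal TP export E (mg/m²) through an Olszewski pipe.
* **Trend engine**: segmented (one-breakpoint) regression à la Muggeo
  with a Davies test and AIC fallback for model choice, permutation
  p-values (B = 10 000), case-resampling bootstrap CIs, detrended lag-1
  correlation for year-to-year feedback, and LMG decomposition of R²
  over all predictor orderings.

A synthetic-lake generator (`limnotrends.synthetic`) produces complete
datasets with analytically known ground truth — seasonal two-layer
thermals, a parametric anoxic-boundary trajectory, breakpointed driver
trends and an AR(1) anoxia→phosphorus feedback — so every stage of the
pipeline is testable without any real data. See `docs/methods.md` for
the model details and design decisions.

## Worked example

```python
import limnotrends as lt

dataset, truth = lt.generate_dataset(seed=1)   # 50-yr synthetic lake
config = lt.AnalysisConfig()
config.stats.b = 999
report = lt.run_pipeline(dataset, config)

m = report.annual_metrics
print(f"S_crit = {report.provenance['s_crit_j_m2']:.2f} J/m^2")
tt = report.trend_table.set_index("series")
for s in ("af", "tp_hypo", "duration"):
    r = tt.loc[s]
    if r["model"] == "segmented":
        print(f"{s}: breakpoint {r['breakpoint']:.1f} (SE {r['breakpoint_se']:.2f}), "
              f"slopes {r['slope_left']:.2f} -> {r['slope_right']:.2f}")
    else:
        print(f"{s}: linear, slope {r['slope_slope']:.2f}/yr "
              f"(95% CI [{r['ci_low_slope']:.2f}, {r['ci_high_slope']:.2f}], "
              f"p = {r['perm_p_slope']:.3f})")
print(f"detrended lag-1 r (AF): {report.lag1['af']['r']:.2f}")
```

prints

```
S_crit = 10.84 J/m^2
af: breakpoint 1998.0 (SE 0.77), slopes -2.16 -> 2.06
tp_hypo: breakpoint 1998.0 (SE 0.64), slopes -0.50 -> 0.22
duration: linear, slope 0.56/yr (95% CI [0.30, 0.81], p = 0.001)
detrended lag-1 r (AF): 0.90
```

Reading it: the generator placed a trend reversal at 1998 in both the
anoxic factor and hypolimnetic TP, and the pipeline recovers the break
year exactly, with the configured slopes (−2/+2 d yr⁻¹ for AF,
−0.5/+0.23 µg L⁻¹ yr⁻¹ for TP) inside the bootstrap intervals. The
stratification season lengthens by ~0.56 d/yr (truth 0.54). The large
lag-1 correlation mixes genuine AR(1) persistence (φ = 0.5) with the
V-shaped residual a linear detrend leaves on a broken trend — the
feedback-isolation experiment in the test suite separates the two.

The same analysis runs from the shell:

```bash
limnotrends synth --seed 1 --out lake/            # 4 CSVs + truth.json
limnotrends analyze --profiles lake/profiles.csv --hypso lake/hypsography.csv \
    --withdrawal lake/withdrawal.csv --inflow lake/inflow.csv --out results/
```

writing `annual_metrics.csv`, `trends.csv`, `correlations.csv`,
`lmg.csv` and `report.json` (with a provenance block sufficient to
re-run bit-identically).

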