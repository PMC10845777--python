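# no2burden

Urban–rural three-stage time-series analysis of short-term nitrogen dioxide
(NO₂) exposure, cardiovascular (CVD) hospital admissions, and the
attributable economic burden.

The package is aimed at environmental epidemiologists who analyse multi-site
county-day panels — daily cause-specific admission counts alongside daily
pollutant concentrations and weather — and want stratum-level (urban vs
rural) health and cost burdens under counterfactual air-quality guidelines.
Because admission records of this kind are rarely shareable, the package
also ships a synthetic-panel generator with known ground truth so the whole
pipeline is testable end to end.

## The model

**Stage 1 — county-level distributed-lag model.** For each county, daily
admission counts Y_t follow an overdispersed (quasi-)Poisson log-linear
model

    log E(Y_t) = α + Σ_{l=0..4} β_l NO₂_{t−l} + DOW + Holiday
                 + ns(time, 7 df/year) + ns(T̄₃, 6 df) + ns(RH̄₃, 3 df)

where DOW are day-of-week indicators (reference Monday), T̄₃ / RH̄₃ are
3-day trailing moving averages of temperature and relative humidity, and
ns(·) are natural cubic splines. Point estimates are Poisson ML; standard
errors are inflated by √(Pearson χ²/(n−p)). Effects are reported per
10 μg/m³: single-day β_l×10, and cumulative lag 0–k as 10×Σβ_l with
variance 1ᵀV1. An optional co-pollutant enters linearly at lag 0, and a
nonlinear variant replaces the linear NO₂ term by a natural spline with
interior knots at 20 and 40 μg/m³.

**Stage 2 — random-effects meta-analysis.** County log-RRs b_c with
variances v_c are pooled as b_c ~ N(μ, v_c + τ²), τ² by REML
(DerSimonian–Laird as an option), reported as percentage change
(e^μ − 1)×100 with normal Wald CIs, plus I² heterogeneity. Urban and rural
pooled estimates are contrasted with Z = (E_u − E_r)/√(SE_u² + SE_r²).
Meta-regression on county covariates (GDP per capita, beds per 1000) and
multivariate pooling of the spline coefficient vectors (meta-smoothing of
the concentration–response curve) are included.

**Stage 3 — attributable burden.** For county c and year i with annual
mean D_ic and admissions N_ic, RR_ic = exp(β·max(D_ic − AQG, 0)/10) and
AN_ic = N_ic (RR_ic − 1)/RR_ic; attributable hospital days and expenses
scale each county's AN by its mean length of stay and mean expense per
admission. AF divides by the stratum-wide outcome total. Guideline
scenarios: AQG = 10 μg/m³ (WHO 2021) and 40 μg/m³ (WHO 2005).

Kaplan–Meier survival curves, a log-rank urban–rural contrast and a
health-service utilization table support the interpretation of burden
disparities.

## Worked example

```python
import no2burden as nb
from no2burden.pipeline import PipelineConfig, run_pipeline

cfg = nb.SimulationConfig(n_urban_counties=10, n_rural_counties=10,
                          n_years=2, lag_weights=(1, 0, 0, 0, 0), seed=7)
sim = nb.simulate_panel(cfg)                     # 20 counties, known truth
res = run_pipeline(PipelineConfig(out_dir="out"), data=sim)

p = res["pooled"][("overall", "cvd", "lag0")]
pct, lo, hi = p.pct
print(f"pooled lag-0: {pct:.2f}% (95% CI {lo:.2f} to {hi:.2f}), "
      f"I2={p.i2:.1f}%, k={p.k}")
```

prints

```
pooled lag-0: 1.20% (95% CI 0.40 to 2.00), I2=8.7%, k=20
```

i.e. the pooled admission increase per 10 μg/m³ NO₂ is 1.20% and its CI
covers the injected truth of 1.42%. The urban–rural contrast for the same
cell gives `Z=0.733, p=0.464` (no true difference was simulated), and the
overall burden rows under the WHO 2021 guideline are

```
stratum cause    outcome  aqg    an  an_lo  an_hi   af  af_lo  af_hi
overall   cvd admissions 10.0  3162   1075   5207 2.99   1.02   4.93
overall   cvd       days 10.0 43382  14749  71444 2.97   1.01   4.90
overall   cvd   expenses 10.0 28455   9674  46860 2.98   1.01   4.91
```

— about 3% of simulated admissions (and the days/expenses they generate)
are attributable to NO₂ above 10 μg/m³ in this world. The same analysis is
available from the shell: `no2burden simulate --out data/ --seed 7` then
`no2burden run --panel data/panel.csv --counties data/counties.csv
--annual data/annual.csv --out out/`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a default synthetic panel from the given seed, runs the full
three-stage pipeline on it (county fits → stratified pooling and
urban–rural tests → guideline burden scenarios), prints the pooled lag-0
effect against the injected truth, and writes the JSON summary to `--out`
with the full report bundle (estimates, pooled effects, difference tests,
burden table, manifest) alongside it.
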