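# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## Stage 1: county distributed-lag quasi-Poisson models

Each county-cause series is fitted independently with a log-link Poisson
GLM whose standard errors are scaled by √(Pearson χ²/(n−p)) — the
quasi-Poisson convention: point estimates are unaffected by
overdispersion, uncertainty is inflated. Fitting is IRLS (statsmodels GLM,
deviance tolerance 1e-8, 100 iterations); non-convergence raises rather
than returning a silent partial fit, and counties whose series leave fewer
than 365 usable days after lag trimming are flagged `excluded` so the
pooling stage can proceed on the remainder with an audit trail.

Design choices:

- **All five single-day lags are estimated jointly** in one distributed-lag
  model with a linear effect at each lag; the cumulative 0–k effect is the
  contrast 1ᵀβ over the first k+1 lag coefficients with variance 1ᵀV1, so
  cumulative 0–0 equals lag 0 identically and cumulative 0–4 equals the
  coefficient sum exactly. Moving-average exposures are fitted as separate
  single-column models when requested.
- **Row loss**: the first max(max_lag, window−1) days of each county are
  dropped entirely (complete-case), keeping exposure lags, the 3-day
  weather moving averages, and the outcome aligned on one index.
- **Natural cubic splines** follow the R `ns` construction: df columns, no
  intercept, df−1 interior knots at quantiles i/df of the *unique* values
  (so duplicated observations cannot move knots), boundary knots at
  min/max, zero second derivative at the boundaries and linear
  extrapolation beyond them. This is hand-built on scipy B-splines because
  no installed package exposes R-style `ns` with explicit interior knots;
  the test suite checks the basis against an independent truncated-power
  construction of the natural-spline space.
- **Calendar adjustment**: 7 df per year for the time spline (rounded half
  up over the actual span n_days/365.25), day-of-week indicators with
  Monday as reference, and a holiday indicator entered additively —
  holidays and weekends may overlap.
- **Per-10 reporting** multiplies coefficient and SE by 10; with a linear
  exposure term this rescaling is exact.
- **Co-pollutant adjustment** enters the second pollutant linearly at
  lag 0 only. Two-pollutant results are conventionally reported at lag 0
  and the co-lag structure is not identifiable from the panel alone.
- **Weather moving averages** use lags 0–2 (the day itself and the two
  previous days), matching the "present and previous days" convention used
  for exposure.

## Stage 2: random-effects pooling

County log-RRs are pooled under b_c ~ N(μ, v_c + τ²). τ² is REML by
bounded scalar minimisation of the restricted negative log-likelihood
(tolerance 1e-10, 200 iterations), falling back to DerSimonian–Laird if
the optimiser fails; DL and a fixed-effect (τ²=0) mode are also exposed.
I² is computed from the fixed-effect Q statistic as max(0, (Q−(k−1))/Q).
All intervals and the urban–rural Z test use the standard normal, not t.
A single-county stratum passes through with τ²=0 and a `degenerate` flag.

Meta-regression adds moderator columns to the GLS mean structure with the
same scalar REML τ²; residual I² uses the fixed-weight residual Q with
k−p degrees of freedom. Collinear moderators (including constants) raise.

Curve pooling (meta-smoothing) treats each county's 3-dimensional spline
coefficient vector θ_c ~ N(μ, S_c + τ²I) with a *scalar* τ²·I
between-county covariance estimated by REML. An unstructured 3×3
between-county covariance is deliberately not attempted: with tens of
counties it is weakly identified, and the implementation instead falls
back to coefficient-wise univariate pooling (with a warning) when the
multivariate REML surface degenerates. Pooled curves are centred to
log-RR 0 at a caller-supplied reference concentration (the pipeline uses
the grand-mean NO₂), and counties must share interior and boundary knots —
the per-county nonlinear fit accepts explicit boundary knots for this.

## Stage 3: attributable burden

RR_ic = exp(β·max(D_ic − AQG, 0)/10) clamps compliant county-years to
RR = 1: a county already meeting the guideline contributes zero, never
negative, burden. AN_ic = N_ic(RR_ic − 1)/RR_ic is summed over
county-years; days and expenses multiply each county's AN by its mean
length of stay and mean expense per admission. AF denominators are
stratum-wide outcome totals over all counties (a flag restricts them to
guideline-exceeding counties for sensitivity). Intervals plug the pooled
β's Wald CI endpoints through the same formulas — the map is monotone in
β, so endpoints stay ordered; no delta method or bootstrap is used.
Reported tables round AN to integers and AF to 2 decimals.

## The synthetic world

The generator emulates what the analysis assumes and nothing more:

- **Exposure**: NO₂ = winter-peaking sinusoid + AR(1) noise, truncated at
  0.1 μg/m³; `no2_sd` is the *marginal* SD target, so the AR(1) variance
  is reduced by the sinusoid's share. Defaults (mean 36.1, SD 16.0, AR(1)
  0.7, seasonal amplitude 10) reproduce daily NO₂ summaries typical of
  northern-China county panels. One co-pollutant is correlated with NO₂ at
  a single configurable ρ (default 0.6); a full multi-pollutant joint
  distribution is not modelled. Temperature is a summer-peaking sinusoid
  (mean 14.8 °C), humidity iid normal clipped to (0, 100).
- **Counts** are negative-binomial — the generative stand-in for
  quasi-Poisson, which has no generative form — with θ =
  baseline_mean/(overdispersion−1) so the Pearson dispersion at the
  baseline mean equals the configured value (default 1.5; 1 gives exact
  Poisson). The log-mean carries the injected distributed-lag effect
  (default 1.42% per 10 μg/m³ across weights (0.6, 0.2, 0.1, 0.07, 0.03);
  negative "displacement" weights allowed behind a flag), day-of-week and
  holiday factors, and a cold/winter confounding term scaled by
  `confounding_strength`. County intercepts are log-uniform around the
  baseline so county sizes differ and meta-analytic weighting is
  exercised. The default baseline (7 admissions/county-day) matches the
  order of magnitude of ~2600 CVD admissions per county-year.
- **Metadata**: urban counties draw longer stays (≈19 vs ≈9 days) and
  higher expenses (≈10.9 vs ≈7.0 thousand CNY per admission) than rural
  ones, plus GDP and bed-density covariates, reproducing the cost
  asymmetry that drives urban–rural burden disparities.
- **Holidays** are a synthetic calendar (10 fixed dates plus a movable
  7-day block per year); no real national calendar is reproduced.
- **Survival**: exponential event times per zone (rural hazard =
  urban × HR), censoring exponential with rate set so the expected
  censored fraction equals `censor_rate`.
- **Determinism**: every stream derives from (seed, county index,
  substream), so identical configs are bit-identical and subsetting
  counties never shifts other counties' draws.

What a green test establishes: that the estimators recover known
generative parameters under the model's own assumptions (correct mean
structure, independent counties, no residual autocorrelation beyond what
the splines remove). What it does not: robustness to exposure measurement
error, spatial correlation between counties, outbreak-like count anomalies
or reporting artefacts — none of which are simulated.

## Numerical and degenerate-input choices

- Perfect fits (constant counts) return dispersion 0 rather than erroring;
  the Pearson scale is applied to the covariance after IRLS.
- Rank-deficient designs raise naming the collinear columns.
- τ² optimisation is bounded in [0, max(10·var, max vᵢ)] and truncated at
  0; Q = 0 defines I² = 0.
- Tied survival times follow the events-before-censorings convention.
- The log of the inverse percentage-change transform uses log1p for small
  effects; round-trips are exact to 1e-12.
- Reported p-values are capped at 1.

## Known limitations

- No autocorrelation-robust standard errors; detrending rests entirely on
  the calendar spline.
- No penalised or cross-basis (nonlinear lag) exposure models; the
  lag-response is linear by design.
- Burden intervals ignore uncertainty in D_ic, N_ic and the cost scalars;
  only the pooled β's uncertainty propagates.
- The meta-smoothing between-county covariance is scalar; genuinely
  anisotropic heterogeneity across the spline coefficients would be
  understated.
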