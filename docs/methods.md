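# Methods

## The two-stage model

**Stage 1 (per municipality).** Daily event counts are regressed on a
cross-basis of daily mean temperature under a time-stratified case-crossover
design. The cross-basis couples a natural cubic spline over temperature
(`var_df` columns, equal-interval knots, no intercept — constants are
absorbed by the strata) with a natural cubic spline over integer lags
0..`max_lag` (interior knots equally spaced on the log-lag scale, intercept
included so lag-0 and cumulative effects are representable). Entry (t, jk)
is Σ_l b_j(x_{t−l}) c_k(l); columns are ordered exposure-fastest and the
ordering is serialized with every fit so the reduction step cannot drift
out of sync. Same-day relative humidity, rainfall, and sunshine enter as
5-df equal-interval natural cubic splines; confounders are not lagged.

Strata are (calendar year, month, day-of-week). Conditioning the Poisson
likelihood on the stratum totals turns each stratum into a multinomial;
maximizing that conditional likelihood is exactly equivalent to a Poisson
regression with one intercept per stratum. The estimator profiles the
intercepts out and runs Newton iterations at the dimension of the
substantive covariates, so hundreds of strata cost nothing. Strata with a
zero total count or a single day carry no information and are dropped
(counted, not imputed). The first `max_lag` days of each series lack a full
lag window and are excluded from fitting.

Overdispersion: counts are treated as quasi-Poisson. The dispersion is the
Pearson χ² over the residual degrees of freedom
n_informative_days − rank(X) − n_informative_strata (the stratum intercepts
are estimated parameters even though they are profiled out), and the
coefficient covariance is the inverse conditional information scaled by it.

**Stage 2 (pooling).** Each fit is reduced to the overall cumulative
exposure–response θ = A η, where A contracts the lag dimension with the
summed lag-basis M_k = Σ_l c_k(l); the covariance maps through the same A.
Units are pooled by an intercept-only multivariate random-effects
meta-analysis, θ_i ~ N(θ, S_i + ψ), ψ estimated by REML (ML and fixed-effect
available). Cochran's Q is computed against the fixed-effect pooled
estimate with weights S_i⁻¹, df = (n_units − 1)·dim(θ), and
I² = max(0, (Q − df)/Q)·100. Per-unit BLUPs shrink each θ_i toward the pool:
BLUP_i = θ̂ + ψ(ψ+S_i)⁻¹(θ_i − θ̂), with prediction covariance
ψ − ψ(ψ+S_i)⁻¹ψ + (I−H)V_pooled(I−H)ᵀ.

**Curves and attributable fractions.** Risk ratios are contrasts of the
cumulative curve against the minimum-risk temperature (MMT): the argmin of
the predicted curve over a 0.1 °C grid between the 1st and 99th percentiles
of observed temperatures, ties broken toward the colder temperature.
Intervals are normal-approximation on the log scale. Subgroup curves are
displayed against the total-population MMT so subgroups share a reference.
The attributable fraction on day t is AF_t = 1 − exp(−logRR(x_t)) against
the unit's own MMT derived from its BLUP curve over its own percentile
band; AN_t = AF_t·y_t, days with RR < 1 contribute negatively (net-AF
convention), and the pooled AF is 100·ΣAN/Σy over all fitted days. The
Monte-Carlo CI resamples each unit's coefficients from
MVN(BLUP_i, vcov_i); the per-unit MMT is held fixed across draws —
re-deriving it per draw would make every simulated AF positive by
construction (each draw's reference would be its own minimum), so a null
effect could never yield an interval covering zero.

## Key parameters

| parameter | default | notes |
|---|---|---|
| `max_lag` | 21 days | captures delayed cold effects; QAIC fell with longer lags in this literature |
| lag knots | grid 1–3 | equally spaced on log-lag; chosen by summed QAIC |
| temperature df | grid 3–5 | equal-interval knots over the pooled range; chosen by summed QAIC |
| confounder df | 5 | humidity, rainfall, sunshine; same-day only |
| percentile band | (1, 99) | MMT search and AF reference window |
| MMT grid resolution | 0.1 °C | configurable |
| `n_sim` | 5000 | Monte-Carlo draws for AF CIs (1000 in the scaled validation studies) |
| meta method | REML | ψ parameterized via its Cholesky factor (PSD by construction) |

**Shared exposure basis.** All units are fitted on one exposure basis with
knots from the pooled temperature distribution. Pooling coefficients
estimated on unit-specific bases would average curves expressed in
different coordinate systems; with heterogeneous unit scales this produced
a measurable bias in the pooled curve during development, so the shared
basis is the pipeline default (unit-specific specs remain available in the
spline layer).

## The synthetic-data generator

The generator emulates the shape of a multi-municipality claims study:
17 units with the published per-unit spans (4–10 years), daily event
scales from 0.3 to 17.4 events/day, and weather marginals matched per unit
(temperature means 16.1–18.4 °C, SDs 7.2–8.6 °C; humidity ≈66–70%;
zero-inflated rainfall with means ≈4–7 mm and heavy right tails; sunshine
≈5–6 h clipped to [0, 14]).

* Temperature = mean + annual cosine (period 365.25 d, trough in late
  January) + AR(1) noise (lag-1 correlation 0.8). The seasonal cycle
  carries 82% of the marginal variance; amplitude and noise SD are backed
  out from the target mean/SD, so generated series match the published
  marginal moments within ±0.5 °C.
* Rainfall is zero-inflated gamma (60% dry days), with the gamma moments
  solved from the target mean and SD — the published SDs are ~3× the means,
  which a Gaussian cannot produce.
* Counts: log-rate = calibrated intercept + annual sine/cosine + weekday
  offsets (sum-zero) + the true surface summed over lags; counts are NB2
  with variance = 1.5 × mean, honoring the quasi-Poisson variance
  assumption of the fitting stage. The intercept is calibrated
  deterministically so the realized mean rate equals the unit's target.
* The baseline's seasonal term is evaluated at each month's midpoint, i.e.
  it is piecewise-constant within calendar months. The (year, month,
  weekday) strata then absorb it *exactly*, which is the identifying
  assumption of the time-stratified design. This is a deliberate generator
  property: it makes the testbed measure the estimator, not the design.
  **Real data offer no such guarantee** — continuous within-month baseline
  drift correlated with temperature is residual confounding that the design
  cannot remove (in development, a continuous seasonal baseline induced a
  spurious cold effect of about −0.1 log-RR at the cold tail). Passing
  tests therefore validate the estimation machinery under the design's
  assumptions, not robustness to their violation.

Truth surfaces ship as parameter blocks (never code): `null`, a lag-0
hockey stick, a hockey stick distributed over lags with geometric decay,
and a smooth quadratic with geometric lag decay. The ground-truth AF is
computed by counterfactual re-evaluation of the analytic rates: the factual
rate keeps the surface, the counterfactual pins every day's summed
temperature contribution at the cumulative curve's value at the true MMT,
burn-in days excluded. This is exact (no simulation error) and is verified
against a day-by-day hand computation in the tests.

In the recovery validation studies the hockey-stick cumulative effect is
allocated *uniformly* over lags 0..21 (geometric ratio 1.0). The cumulative
curve — the quantity those studies test — is invariant to the truth's lag
allocation, but spiky allocations lie outside the natural-spline lag basis
and their approximation error leaks into the cumulative cold tail
(−0.04..−0.08 log-RR measured for decay ratios 0.3–0.7); the in-span
allocation keeps the test aimed at cumulative recovery. Out-of-span lag
shapes remain available as presets and are a documented limitation.

## Numerical choices

* Newton iterations on the profiled likelihood with step-halving; under
  quasi-separation (e.g. zero-count heavy-rain days) some coefficients
  drift unboundedly while the likelihood plateaus, so convergence is
  declared on the likelihood, separated days contribute zero to the
  Pearson statistic in the (y=0, μ→0) limit, and the affected directions
  carry honest, huge variances through the pseudo-inverse.
* Collinear columns are detected on the within-stratum-centered design by
  pivoted QR and dropped with their indices reported; dropped columns get
  zero coefficient and zero variance rows.
* QAIC = −2ℓ/φ_ref + 2k with ℓ the conditional log-likelihood (the
  y-only multinomial constant is omitted — it cancels in all differences)
  and φ_ref taken from each unit's richest-model fit.
* REML optimization runs L-BFGS-B (Nelder-Mead fallback) from two starts —
  the method-of-moments estimate and a near-zero matrix — keeping the
  better objective and, on ties, the smaller-trace ψ: in directions where
  within-unit covariances dominate, the likelihood is flat in ψ and the
  start would otherwise dictate spurious heterogeneity. Non-convergence
  falls back REML → ML → method-of-moments, recorded in the result.
* Non-PSD covariances entering the Monte-Carlo step are repaired by
  clipping negative eigenvalues at zero.
* All randomness flows from a single master seed through spawned
  SeedSequences; reruns are byte-identical.

## Known limitations

* **AF reference selection bias.** The AF reference is the argmin of an
  estimated curve — an extreme-value functional. When the true curve has a
  flat region (any hockey-stick truth), the argmin sits in the deepest
  noise dip, typically near the cold boundary where the curve's standard
  error is largest, shifting every day's log-RR upward. At small study
  sizes (tens of thousands of events) this inflates the pooled AF by
  several percentage points and degrades the calibration of the
  Monte-Carlo CI, which resamples coefficients around the already-selected
  reference and cannot undo the selection. The synthetic ground truth makes
  this visible; applied studies using this methodology report AFs subject
  to the same effect. The validation studies in `scripts/acceptance.py`
  report both the estimated and the true AF so the gap is measurable rather
  than hidden.
* Between-unit heterogeneity is estimated in coefficient space; directions
  poorly identified within single units (near-collinear basis columns) can
  show coefficient-level heterogeneity without curve-level meaning.
* The lag basis cannot represent sharply concentrated lag structures
  (e.g. a pure lag-0 spike) exactly; misfit leaks into the cumulative
  curve's tails.
* No penalized smoothing; dimensions come from the QAIC grid only.
* The generator draws weather covariates independently of temperature;
  confounding structure among weather variables is not emulated.

## Validation study sizes

The recovery study uses 10 units × 6 years at ~2 events/day (≈44,000
events) averaged over 5 master seeds; the null calibration uses 100
replicates of 5 units × 3 years. These sizes keep the full validation,
including Monte-Carlo CIs, under a minute of CPU while leaving the pooled
curve's confidence band informative at the tails.
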