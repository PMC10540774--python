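# Methods

## The problem

Estuary water quality responds to nutrient loads delivered by rivers, but
loads themselves are dominated by year-to-year variation in precipitation and
runoff. To tell management-driven change from weather, the pipeline (1)
estimates riverine nutrient loads from sparse ambient concentration samples
and daily discharge, (2) removes the discharge-driven variability from those
loads ("flow normalization"), and (3) asks whether seasonally adjusted
freshwater inflow — and flow-normalized loads beyond it — explain variation in
estuary constituents.

## Stage 1: the concentration rating model

Discrete concentrations y (mg/L) are modeled as Gaussian with a log link:

    log E[y] = α + f1(ddate) + f2(yday) + f3(log(1+Q)) + f4(ma) + f5(fa)

* `ddate` — decimal date, `year + (day_of_year − 1)/days_in_year`; captures
  the long-term trend.
* `yday` — day of year (1–366), fit with a cyclic cubic spline so day 1 and
  day 366 join; captures seasonality.
* `log(1+Q)` — transformed mean daily discharge (cfs). `log1p` keeps
  zero-flow days defined; plain `log` with an offset is available.
* `ma` — discounted moving average of transformed flow,
  `ma(t) = (x_t + d·x_{t−1} + … + d^{t−1}·x_1)/(1 + d + … + d^{t−1})`,
  default discount d = 0.95; antecedent wetness. At d = 0 this is the daily
  value, at d = 1 the running record mean. Computed by a streaming recursion
  (two first-order IIR filters), numerically identical to the direct sum.
* `fa` — a flow anomaly. The long-term anomaly (`ltfa`, used for nitrate) is
  the mean transformed flow over the 365 days ending at t minus the
  whole-record mean; the short-term anomaly (`stfa`, used for TP) is day t's
  transformed flow minus the mean over the 30 days ending at t − 1 (the
  current day is excluded so the "today vs the past month" contrast is
  clean). Days with less than the full window are computed over available
  history and flagged; the whole first year of record is flagged as warm-up
  and excluded from fitting by default.

The Gaussian-with-log-link family is deliberate: the response stays on the
natural scale, so no retransformation bias correction is needed when
exponentiating the linear predictor.

Left-censored samples (< detection limit) are substituted at one-half the
detection limit before fitting, with the censoring flag preserved for audit.
This simple substitution is acceptable for load estimation because loads are
dominated by high-flow, high-concentration events, not censored low-flow
samples.

### Fitting engine

Models are penalized GLMs fit by `statsmodels` `GLMGam` (penalized IRLS).
Smooth terms are low-rank penalized B-splines: cubic B-spline bases (default
dimension 10 for the trend and flow terms, 8 for season) with derivative
penalties — second order (curvature) for the trend, first order for the three
flow-derived terms, so flow smooths are shrunk toward *flat* functions and
cannot extrapolate wildly at unsampled high flows. The `thin_plate` basis
name is accepted for these one-dimensional smooths; a genuine thin-plate
basis offers no practical advantage in 1-D and none is available in the
installed stack. All smooths are centered (sum-to-zero), leaving the level to
the intercept.

Smoothness is selected automatically by minimizing, over log penalty weights,
either a Laplace-approximate REML score with the scale profiled out
(`(n − Mp)·log(Dp) + log|X'WX + S| − log|S|₊`, the default) or GCV
(`n·D/(n − edof)²`). The optimizer is Nelder-Mead started from the best point
of a coarse global grid; every step is deterministic, so refits on identical
inputs reproduce coefficients to machine precision. Basis dimensions are
generous relative to quarterly data; penalization controls effective
complexity (a null effect shrinks to ~0 effective degrees of freedom).

**Prediction clipping.** Predictions clip each non-cyclic covariate to the
range observed in the calibration samples and hold the smooth flat beyond
it. Ambient quarterly sampling never observes the most extreme flow days, the
data carry no information about the response shape there, and an unclipped
spline tail — harmless on the log scale — dominates everything once
exponentiated and multiplied by an extreme discharge (posterior draws of
annual load were observed 13 orders of magnitude above the plug-in estimate
without clipping). The cost is a conservative (flat) concentration-flow
relation beyond the sampled range; the daily *load* still scales linearly
with that day's discharge.

### Loads, flow normalization, uncertainty

Daily load (kg/day) = predicted concentration (mg/L) × discharge (cfs) ×
2.446576 (= 28.316846592 L/ft³ × 86400 s/day × 10⁻⁶ kg/mg). Annual loads sum
complete calendar years; partial years are excluded and reported. For
reservoir outlets, rating-model covariates are built from total tributary
inflow while the mass conversion uses the reported dam release
(`lake_outlet_daily_load`).

Flow normalization: for each day t, every flow-covariate tuple
(log1pQ, ma, fa, plus that day's discharge) observed on the same calendar day
in every year of the record is substituted in turn, with trend and season
held at day t, and the predicted loads are averaged. Feb 29 pools with
Feb 28's history so no calendar day rests on a single tuple. By default each
historical tuple's own discharge multiplies its predicted concentration
(normalizing over the joint flow distribution); `normalize_load_flow=False`
multiplies the flow-normalized concentration by day t's own discharge
instead.

Uncertainty: coefficient vectors are drawn from the multivariate normal
posterior N(β̂, Vb), Vb = φ·(X'WX + S)⁻¹ at convergence; the annual (or
flow-normalized annual) load is recomputed per draw; the posterior SD and
central 90% interval are reported alongside the plug-in estimate (default
1000 draws, seeded). This propagates coefficient uncertainty only — smoothing
parameters are treated as fixed, the usual simplification.

## Stage 2: estuary response models

Each estuary constituent (TP, NOx, TKN, chlorophyll-a, DO) is modeled as
Gamma with a log link — appropriate for positive right-skewed concentrations,
and applied uniformly to DO as well for consistency even though DO is not
right-skewed. The nested set per constituent:

| Model     | Linear predictor                                         |
|-----------|----------------------------------------------------------|
| Temporal  | α + f(ddate) + f(yday)                                   |
| Flow      | … + f(adjusted 20-day cumulative inflow)                 |
| Flow+Load | … + f(20-day cumulative flow-normalized load(s))         |

TKN has no load model (no organic-nitrogen load series exists); TP and NOx
carry only their matching load; chlorophyll-a and DO carry both TP and NO3
load smooths. The 20-day window reflects the persistence of storm effects on
estuary water quality; the window includes the sample day.

Because cumulative inflow is tightly seasonal and loads are tightly coupled
to flow, inflow enters as the *residual* of a cyclic seasonal fit to
log1p-transformed 20-day cumulative inflow (log1p because a fully dry window
is a legitimate zero), and loads enter flow-normalized — so the load smooth
reflects management-driven rather than runoff-driven variation.

Models are compared with AICc, `AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1)`, with
k = effective degrees of freedom + 1 for the scale parameter (the standard
choice for semiparametric models, where a fixed parameter count is not
defined), and
Akaike weights `w_i ∝ exp(−Δ_i/2)` computed stably via max subtraction. All
models in a set are fit on identical rows. When an added smooth is penalized
to null the richer model collapses onto the simpler one and the AICc values
effectively tie; the flagged best model is then the simplest within 0.5 AICc
of the minimum — far below the Δ ≈ 2 threshold usually read as "substantial
support" — while the near-equal weights are reported untouched.

## Synthetic data: what it emulates and what it does not

`generate_discharge` produces lognormal daily flow: seasonal sinusoid
(amplitude 0.8 log units), AR(1) persistence (φ = 0.85, innovation SD 0.3)
and exponentially decaying event pulses (rate 0.02/day, Exponential(1.0)
magnitudes, 7-day e-folding). Defaults give mean ≈ 190 cfs with SD ≈ 5× the
mean and strong skew — the character of the coastal-plain gauge records this
pipeline targets. It does not emulate reservoir routing, tidal backwater or
multi-gauge spatial correlation.

`generate_concentration_samples` draws roughly quarterly samples (default
91-day interval, 16–21 year windows, n ≈ 50–80) with additive Gaussian noise
on the natural scale (floored at 10⁻⁶ mg/L) and left-censoring at a detection
limit; generated series carry their effect functions so tests can evaluate
truth on any day. `generate_estuary_samples` draws Gamma samples whose
log-mean follows trend + season + adjusted-inflow + load effects.

Passing tests on these generators demonstrate that the *machinery* recovers
known structure under realistic sparsity, noise, skew and censoring; they say
nothing about unmodeled features of real monitoring data (flow-biased
sampling gaps, method changes, matrix effects, tidal variability).

## Numerical choices and scenario sizes

* Penalties are Frobenius-normalized per term so one optimizer scale serves
  all terms; optimizer budget is capped (`optimizer_maxfev`), and simulation
  studies use reduced caps (25–80 evaluations) — selection quality degrades
  gracefully because ties are handled explicitly.
* Simulation studies use 17-year records with quarterly sampling (n = 65):
  calibration coverage and flow-normalization stabilization run 200
  replicates in the test suite (60 in the acceptance script), selection
  consistency 100 per truth class (30 in the script).
* Posterior draws: 300–1000 depending on context; draw-count stability is
  checked (8000 vs 1000 endpoints agree within 2%).
* Degenerate inputs: constant covariates are rejected with the term named;
  non-PSD posterior covariance raises with a repair hint (eigenvalue clipping
  is opt-in); metrics raise `UndefinedMetricError` on constant observations
  rather than returning NaN silently; CV folds whose metrics are undefined
  are reported as missing, not dropped.

## Known limitations

* Censoring is handled by half-DL substitution (as specified), not by a
  censored likelihood; at high censoring rates this biases low-flow
  concentrations.
* REML here is the Laplace/profiled approximation at PIRLS convergence, not
  an exact restricted likelihood; it behaves like one (shrinks null terms,
  tracks signal) but its absolute value is not comparable across engines.
* Coefficient-posterior intervals ignore smoothing-parameter uncertainty and
  are conditional on the clipping rule; coverage is verified by simulation
  (80–97% band) rather than asserted.
* Flow normalization assumes the historical same-calendar-day flow
  distribution is a fair reference — a stationarity assumption over the
  record span.
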