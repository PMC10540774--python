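# estuarylink

Estimate riverine nutrient loads from sparse water-quality samples and daily
discharge, separate weather-driven from management-driven load variation by
flow normalization, and test whether freshwater inflow and watershed nutrient
loads explain estuary water-quality variation.

The package is aimed at water-quality analysts working with ambient
monitoring data: roughly quarterly grab samples of nutrient concentrations
(TP, nitrate, …) at river gauges, continuous daily discharge, and estuary
constituent samples downstream.

## The models

**Stage 1 — load estimation.** Concentration is related to time, season and
antecedent discharge through a penalized additive model with a log link,

    log E[y] = α + f₁(ddate) + f₂(yday) + f₃(log(1+Q)) + f₄(ma) + f₅(fa),
    y ~ N(μ, σ²),

where `ddate` is decimal date, `yday` day of year (cyclic spline), `Q` mean
daily discharge (cfs), `ma` a discounted moving average of log-transformed
flow (discount d = 0.95) and `fa` a long- or short-term flow anomaly
(trailing year vs whole record for nitrate; current day vs trailing month for
TP). Censored values enter at half the detection limit. Daily load is
predicted concentration × discharge × 2.446576 kg·day⁻¹/(mg·L⁻¹·cfs).
Flow-normalized loads average each day's prediction over all flow conditions
historically observed on that calendar day; 90% credible intervals come from
simulating the coefficient posterior. Skill is assessed by repeated 5-fold
cross-validation with NSE, Pearson r and percent bias.

**Stage 2 — estuary response.** Each estuary constituent is modeled as Gamma
(log link) with a nested model set — Temporal (trend + season), Flow
(+ seasonally adjusted 20-day cumulative inflow), Flow+Load (+ 20-day
cumulative flow-normalized loads) — compared by AICc and Akaike weights
(model probabilities).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import estuarylink as el

# a synthetic 17-year study: skewed seasonal discharge, quarterly TP samples
flow = el.generate_discharge(el.FlowGenConfig(seed=3, n_years=17))
samples = el.generate_concentration_samples(flow, el.ConcGenConfig(
    seed=5, intercept=np.log(0.2),
    season_fn=lambda yd: 0.2 * np.sin(2 * np.pi * yd / 366),
    flow_fn=lambda x: 0.3 * np.tanh(x - 5.0),
    ma_fn=lambda m: 0.1 * np.tanh(m - 5.0),
    noise_sd=0.04))

cov = el.build_covariates(flow, "ltfa", d=0.95)   # per-day design table
model = el.fit_concentration_model(el.substitute_censored(samples), cov)
print({k: round(v, 2) for k, v in model.edof_per_term.items()})

days = cov[~cov.warmup].reset_index(drop=True)
annual = el.posterior_annual_intervals(model, days, n_draws=1000, seed=1)
fn = el.aggregate_annual(el.flow_normalize(model, days), "fn_load_kg")
print(annual.head(3).round(0).to_string(index=False))
print("delivered CV %.2f   flow-normalized CV %.3f" % (
    annual.load_kg.std() / annual.load_kg.mean(),
    fn.fn_load_kg.std() / fn.fn_load_kg.mean()))
```

prints

```
{'ddate': 1.35, 'yday': 2.88, 'log1pQ': 5.02, 'ma': 0.0, 'fa': 0.0}
 year  load_kg  posterior_mean     sd  lower90  upper90
 2001  47932.0         48381.0 3048.0  43681.0  53700.0
 2002  23760.0         23862.0 1267.0  21898.0  26041.0
 2003  28845.0         29001.0 1474.0  26601.0  31478.0
delivered CV 0.32   flow-normalized CV 0.051
```

Read it as: the season and flow smooths carry 3–5 effective degrees of
freedom while the unused anomaly terms are penalized to null; 2001 delivered
about 48 t of TP with a 90% interval of 44–54 t; and once discharge-driven
variability is averaged out, annual loads are nearly flat (CV 0.051 vs 0.32)
— this generating model had no management trend, and the flow-normalized
series says so.

The same pipeline runs from the shell:

```bash
estuarylink simulate --seed 3 --out work
estuarylink fit-load --config config.yaml --seed 3
estuarylink estuary-compare --estuary-samples bay.csv --inflow q1.csv \
    --inflow q2.csv --fn-loads TP work/fn_daily_loads.csv --parameter TP
```

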