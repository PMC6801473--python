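# thermoyll

Distributed-lag non-linear modelling of the effect of ambient temperature on
daily **years of life lost (YLL)**.

Time-series studies of temperature and health usually model daily death
counts, which weight every death equally. YLL weights each death by the
life-table expected remaining life years at the decedent's age and sex, so
deaths of younger people count for more. This package provides the full
analysis chain for a temperature–YLL study in a single city:

* **YLL engine** — per-death YLL from period life tables (long CSV:
  `year,sex,age,ex`) and daily aggregation into strata (all, by gender, by
  age <65/≥65, cardiovascular I00–I99 and respiratory J00–J99 among the
  elderly, non-accidental A00–R99).
* **DLNM core** — distributed-lag non-linear model (DLNM) with hand-built
  spline bases: the temperature cross-basis pairs a quadratic B-spline over
  temperature (knots equally spaced across its range) with a natural cubic
  spline over log(lag+1) (knots equally spaced on the log scale), lags 0–30.
* **Effects** — cold (25th→1st temperature percentile) and heat (75th→99th)
  contrasts, single-day and cumulative, with delta-method 95% CIs, plus the
  table-style summaries used in this literature ("Lag 5–14, lag 23–29").
* **Synthetic data** — a registry-style generator with a known
  exposure–lag–response truth, so estimator calibration (bias, CI coverage,
  type-I error) is testable without access to restricted mortality data.

## The model

For day *t* of an *n*-day series (identity link, Gaussian errors; daily YLL
is approximately normal):

```
E(YLL_t) = cb(temp; lag 0–30) + Σ_p cb(pollutant_p; lag 0–1)
         + ns(time, 7 df/year) + ns(humidity, 3 df) + DOW + holiday + α
```

where `cb(x)` is the cross-basis with design entries
`CB[t, jk] = Σ_l R_j(x_{t−l}) C_k(l)` (R over exposure values, C over lags).
An effect for a temperature contrast (target vs reference) at lag *l* is the
linear functional `v'β` with `v = (R(target) − R(ref)) ⊗ C(l)` on the
temperature block, with variance `v'Σv`; cumulative effects sum the per-lag
contrast vectors, so on the identity link the cumulative estimate is exactly
the sum of single-lag estimates.

## Worked example

```python
from thermoyll import (SimulationConfig, TemperatureYLLModel,
                       make_cold_heat_truth, simulate_daily_series)

truth = make_cold_heat_truth()           # delayed cold + immediate heat effect
daily = simulate_daily_series(SimulationConfig(seed=42, truth_surface=truth))
res = TemperatureYLLModel.from_dataframe(daily, response="all").fit()
print(res.summary())
```

prints

```
Temperature-YLL distributed-lag model (Gaussian, identity link)
================================================================
response: all    days used: 1431    residual SD: 59.75 years
max lag: 30    temp basis: quadratic B-spline df=5    lag basis: ns(log(lag+1)) df=5
time trend: 7 df/year    humidity: 3 df    pollutants: pm10, no2, so2, co, o3
cold contrast: 3.40 -> -6.21 C (25th -> 1st pctl)
heat contrast: 19.15 -> 28.58 C (75th -> 99th pctl)
----------------------------------------------------------------
cold cumulative YLL (lag 0-30): 151.54 (17.18, 285.90) *
  single-day significant duration: Lag 8–22, lag 30; strongest: Lag 13; highest YLL: 15.08 (9.08, 21.09)
heat cumulative YLL (lag 0-30): 73.31 (-19.79, 166.42)
  single-day significant duration: Lag 1–3, lag 6–7; strongest: Lag 1; highest YLL: 41.17 (30.00, 52.34)
```

Reading this: over the 1431 analysed days (the first 30 lack lag history),
a drop from the 25th to the 1st temperature percentile is associated with a
cumulative 151.5 (95% CI 17.2–285.9) extra years of life lost per such day
over the following month — significant (`*`), delayed (single-day effects
significant from lag 8), and of the order of the generating truth for this
series (201.4 years). The heat contrast acts immediately (strongest at lag
1) but its 31-day cumulative total is not significant in this realization.
`res.lag_curve("cold")`, `res.plot_lag_curve(...)` and
`res.summary_table(...)` expose the curves, plots and table rows;
`thermoyll.run_sensitivity` re-fits over the usual reliability grid
(max lag 15–30, time 6–10 df/year, humidity 3–5 df, with/without pollutant
control).

A command-line pipeline wraps the same functions:

```sh
thermoyll simulate --seed 1 --out daily.csv
thermoyll fit --series daily.csv --out fit.json
thermoyll effects --series daily.csv --contrast cold --cumulative --out cold.csv
thermoyll report --series daily.csv --out-dir report/
```

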