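# Methods

## Outcome: daily years of life lost

For one death, YLL is the period-life-table expected remaining life years
`ex` at the decedent's completed age, sex and year of death; daily YLL is
the sum over that day's deaths. Conventions:

* **Year matching.** The death year's table is used when available;
  otherwise the latest earlier available year (e.g. 2016 tables for 2017
  deaths when 2017 tables are not yet published). A death year predating
  all tables is clamped up to the earliest table — the symmetric rule —
  rather than rejected.
* **Age matching.** Completed years, direct row lookup, no interpolation
  between ages. Ages above the table maximum use the terminal open age
  group, so no death is dropped.
* **Strata.** Gender; age at death <65 vs ≥65 (65 assigned to ≥65);
  cause groups by ICD-10 chapter — non-accidental A00–R99, cardiovascular
  I00–I99 and respiratory J00–J99 (both subsets of non-accidental),
  everything beyond chapter R (injuries, external causes) "other".
* No discounting or age-weighting: YLL is plain remaining life expectancy.

## Regression model

Daily YLL is approximately Gaussian at city scale (a sum of many per-death
values), so the model is a linear Gaussian regression on:

* the **temperature cross-basis**, lags 0–30 days: exposure dimension a
  quadratic B-spline with 5 columns (3 interior knots equally spaced over
  the temperature range — *not* at quantiles); lag dimension a natural
  cubic spline with intercept, 5 columns, in log(lag+1) with 3 interior
  knots equally spaced on that log scale (log(lag+1) keeps lag 0 finite);
* one **pollutant cross-basis** per pollutant (PM10, NO2, SO2, CO, O3):
  natural cubic spline in concentration (3 df) × unconstrained indicator
  strata at lags 0 and 1 ("simple lag 0–1": a 2-day window leaves no room
  for smoothing);
* a natural cubic **time trend**, 7 df per year (28 df over four years),
  knots equally spaced over the day index;
* natural cubic **humidity** spline, 3 df;
* 6 day-of-week indicators (Sunday reference — temperature contrasts are
  invariant to the reference, which is tested) and a holiday indicator
  (omitted when no day is flagged, to keep the design full rank);
* an intercept.

The exposure-basis df (5 for temperature, 3 for pollutants) and the lag-df
(5) are configuration defaults in the 4–6 df range that is standard in this
literature; family and knot-spacing rules are fixed, counts are knobs.

Rows without a complete 30-day temperature history (the first 30 days) are
dropped, never imputed. Estimation is ordinary least squares via
statsmodels, with covariance `s²(X'X)⁻¹`, `s² = RSS/(n−p)`. No residual
autocorrelation correction is applied beyond the time spline. Rank
deficiency raises an error identifying the collinear block.

## Spline construction

Both basis families are built from first principles:

* **B-splines** by the Cox–de Boor recursion on a clamped knot vector
  (boundary knots repeated degree+1 times); derivatives by the analytic
  knot-difference recursion. Out-of-range values are clamped to the
  boundary with a warning — needed when contrast percentiles sit at the
  data extremes — rather than evaluated as zero.
* **Natural cubic splines** as the null space of the two boundary
  second-derivative constraints applied to the cubic B-spline coefficients
  (numerically stable; any equivalent parameterization gives identical
  fitted values, which is tested, not assumed). Without intercept the
  constant direction is additionally projected out. Beyond the boundary
  knots evaluation continues linearly (first-order expansion from the
  boundary), the defining property of the natural spline.
* Given df instead of knots, interior knots are placed at equally spaced
  values between the boundary knots (default: data min/max).

## Effect estimation

Cold = temperature falling from the 25th to the 1st percentile of the full
observed series (all days, including the first 30); heat = rising from the
75th to the 99th. Quantiles use linear interpolation between order
statistics (the common software default; recorded in output metadata).
Effects are delta-method linear functionals of the temperature block
(±1.96·sd for 95% CIs, exact under the Gaussian OLS model). Cumulative
effects use the summed contrast vector, so the variance accounts for
cross-lag coefficient covariance.

Summaries follow the field's table notation: maximal runs of consecutive
significant lags ("Lag 5–14, lag 23–29"; "-" when none), the strongest
effect chosen among significant lags only (ties to the smaller lag), and
for cumulative curves the window notation "Lag 0–a to b" meaning windows
0–a through 0–b are all significant. No multiplicity adjustment is applied
across lags or subgroups; CIs are pointwise.

## Synthetic-data generator

The generator emulates a four-year (n = 1461) daily series from a cold-
winter, mild-summer continental city:

* **Temperature**: annual cosine (mean 11.4 °C, amplitude 12.5 °C, peak
  mid-July) plus AR(1) noise (φ = 0.7, innovation SD 2.4 °C, stationary
  initialization), giving series SD ≈ 9.4 °C and range ≈ −12 to 31 °C,
  matching the emulated study's observed moments.
* **Humidity**: Gaussian around 51.5% (SD 14) with a small seasonal term,
  clipped to [0, 100].
* **Pollutants**: log-normal, calibrated so means sit near the emulated
  series (e.g. PM10 ≈ 125 µg/m³), with negative temperature coupling for
  combustion pollutants and positive for ozone.
* **Daily YLL**: baseline 420.5 years/day plus the truth-surface
  contribution, optional trend and pollutant terms, and homoscedastic
  Gaussian noise. The default noise SD of 60 years makes the default cold
  effect clearly detectable in one four-year series (cumulative CI
  half-width ≈ 100 years against a ≈ 200-year truth) while leaving
  single-lag effects realistically uncertain. The emulated total SD
  (≈ 129) includes seasonal structure that here comes from the temperature
  effect itself.
* **Death records** (optional long path): Poisson daily counts (mean 29.4),
  74.6% of deaths at ages ≥65, categorical ICD-10 causes, plus a synthetic
  life table (smooth, strictly decreasing `ex`, females above males).

The **truth surface** f(temperature, lag) is expressed as a contrast from a
reference temperature (so f(ref, l) = 0). Default: a piecewise-linear cold
term below 2.45 °C with a raised-cosine lag profile over lags 5–20 and a
heat term above 19.7 °C over lags 0–2, scaled to cumulative contrasts of
250 (cold) and 90 (heat) years at the nominal percentile pairs, then
**projected onto the model's own cross-basis family with fixed boundary
knots (−20, 36 °C)**. Projection makes the truth exactly representable, so
a model sharing those boundary knots recovers it without approximation bias
— this is what calibration tests measure. The smooth cold profile survives
projection nearly unchanged (≈ 1% on the cumulative contrast); the sharp
3-day heat spike is smeared across the first week by the 5-df log-lag
basis, and the recorded (projected) surface is the recovery target. A
closed-form, unprojected option supports misspecification studies.

What passing tests show — and do not show. The generator matches first and
second moments and a known delayed effect; it is homoscedastic, has no
residual autocorrelation in YLL beyond what temperature induces, no
overdispersion, no harvesting beyond the configured surface, and no spatial
structure. Calibration results (95% CI coverage, ~5% type-I error)
demonstrate the estimator is correct under its own assumptions, not that
those assumptions hold for any real registry.

## Numerical and design choices

* Percentile contrasts can fall outside a replicate's observed range;
  basis evaluation clamps at the boundary knots with a warning rather than
  extrapolating a polynomial.
* Constant covariates widen their degenerate knot range by ±0.5 to keep
  bases well-defined.
* All randomness flows from one integer seed; each generator stage uses an
  independent seeded stream, so weather is bit-identical whether or not
  pollutants are generated.
* Replicate studies in the test suite and the acceptance script use 100–500
  replicates of the full 1461-day fit — large enough for the binomial bands
  on coverage and type-I error, small enough to run routinely.
* The command-line layer is a thin wrapper; the Model/Results objects are
  the primary interface.

## Limitations

Single-city, single-exposure design; no attributable-fraction
decomposition; no penalized or periodic splines; Gaussian errors only (no
quasi-Poisson count path); no meta-analytic pooling. The year-matching and
age-clamping rules above are sensible defaults where registry practice
varies.
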