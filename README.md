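# lakecast

Evaluation toolkit for probabilistic lake water-quality forecasts: the
scoring, baseline, and synthesis machinery of a community forecasting
challenge, plus a fully seeded synthetic challenge generator for
exercising it end to end.

## The problem

Near-term (1–30 days ahead) forecasts of daily surface mean water
temperature and dissolved oxygen are submitted by many independent
models — process-based heat-budget models, machine-learning regressions,
empirical/seasonal models, multimodel ensembles — each carrying its own
representation of uncertainty (driver, parameter, process,
initial-condition, observation). Comparing them fairly requires:

* a **proper score** for probabilistic forecasts. lakecast uses the
  continuous ranked probability score,

  $$\mathrm{CRPS}(F, y_{\mathrm{obs}}) = \int \bigl(F(y) - H(y - y_{\mathrm{obs}})\bigr)^2\,dy,$$

  in variable units (°C or mg L⁻¹), with the closed form for
  normal-family forecasts and the empirical-CDF estimator for
  ensemble-family forecasts;
* a **null model** to measure gains against: a day-of-year (DOY)
  climatology (historical mean ± SD for each calendar day, per site and
  variable, assumed normal) and a persistence baseline. Relative skill
  is the difference
  $\mathrm{CRPS_{skill}} = \mathrm{CRPS_{model}} - \mathrm{CRPS_{DOY}}$,
  negative when the model beats climatology;
* **reliability**: the fraction of observations inside the central 80%
  and 95% forecast intervals, versus the nominal level (under- vs
  over-confidence);
* **inclusion rules** that keep comparisons fair: models must score at
  least 80% of evaluated days (days with observations) per site and
  variable, and a corrupted forecast horizon (day 16) is excluded.

Real challenge submissions live in external archives; lakecast's
`synthetic_challenge` module generates a statistically analogous world —
seasonal lake cycles with AR(1) anomalies, site-years diverging from
climatology, winter ice gaps, 2-day data latency, a 31-member
pseudo-weather ensemble with horizon-dependent error growth, and
stylized model classes — so every synthesis statistic can be tested
against known ground truth.

## Worked example

Run the shipped challenge-shaped configuration (seven lakes, two with a
warm-spring anomaly year, five stylized models plus the two baselines):

```python
import lakecast as lc

config = lc.example_challenge_config()
bundle = lc.run_synthetic_challenge(config, seed=1, out_dir="results/run1")
print(bundle["leaderboard"].to_string(index=False))
```

```
       model_id    variable  crps_skill     crps  abs_bias  forecast_sd    n
       gbm_like      oxygen   -0.126880 0.203881  0.258499     0.532504 7348
   harmonic_reg      oxygen   -0.058215 0.272547  0.375743     0.423987 7348
    climatology      oxygen    0.000000 0.330761  0.446359     0.433524 7348
pb_baseline_mme      oxygen    0.000379 0.331140  0.446359     0.431771 7348
    persistence      oxygen    0.181026 0.511788  0.717202     0.756131 7348
     lasso_like temperature   -0.503453 0.554789  0.540442     1.774633 7300
       gbm_like temperature   -0.487809 0.570434  0.547377     1.926446 7300
  heat_exchange temperature   -0.487107 0.571135  0.536667     1.898703 7300
pb_baseline_mme temperature   -0.391446 0.666796  0.830663     1.972487 7300
   harmonic_reg temperature   -0.175713 0.882529  1.225170     1.313980 7300
    climatology temperature    0.000000 1.058243  1.449601     1.478243 7300
    persistence temperature    0.862350 1.920593  2.594398     1.895570 7300
```

Reading the table: `crps_skill` is the mean CRPS difference against the
DOY climatology over all scored (site, issue date, horizon) rows —
negative means the model added information beyond the seasonal null.
Here the weather-driven models beat climatology by ≈0.5 °C of CRPS on
average, the persistence null is far worse than climatology at the
monthly-and-beyond horizons that dominate the mean, and the DOY row is
exactly zero by construction. `n` counts scored forecast-days after the
inclusion rules (horizon 16 removed, 80%-of-days rule applied).

Per-site summaries show the headline pattern: at the two anomaly-year
lakes (`PRA1`, `PRA2`) the DOY baseline's CRPS is largest and the
process model's relative skill is strongest, because the focal year
diverges from the climatology the null model memorized:

```python
sbs = bundle["skill_by_site"]
print(sbs[(sbs.model_id == "heat_exchange") & (sbs.variable == "temperature")])
```

The same experiment runs from the shell:

```sh
lakecast run --seed 1 --out results/run1       # shipped config
lakecast example-config --out my.yaml          # edit, then:
lakecast run --config my.yaml --seed 1 --out results/run2
lakecast report --in results/run1
```

plus the building-block commands `validate`, `make-targets`, `baseline`,
`score`, and `evaluate` for working with standalone CSV files.

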