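# Methods

This note documents the statistical machinery implemented in lakecast,
the synthetic world used to exercise it, and the design choices made
where the design was genuinely open.

## Scoring

**CRPS.** The continuous ranked probability score of a forecast CDF *F*
against an observation is the integrated squared difference between *F*
and the observation's step function. It is proper, generalizes absolute
error, and is reported in the units of the variable. Two estimators:

* *Normal family* (`crps_normal`): the Gneiting–Raftery closed form
  σ[z(2Φ(z) − 1) + 2φ(z) − π^(−1/2)], z = (y − μ)/σ. σ = 0 degenerates
  continuously to |μ − y|. Unit tests verify agreement with direct
  numerical quadrature of the defining integral to 10⁻⁶.
* *Ensemble family* (`crps_ensemble`): the empirical-CDF ("NRG") form
  mean|xᵢ − y| − (1/2m²)ΣΣ|xᵢ − xⱼ|, computed in O(m log m) via the
  sorted-member identity. This matches the default of the reference R
  implementation ecosystem for ensemble scoring; the bias-corrected
  "fair" variant (divisor m(m−1)) is available behind a flag. Tests
  verify exact agreement with the brute-force double sum and
  convergence to the normal closed form as m grows (error ~ m^(−1/2)).

**Score table.** Forecasts are inner-joined to observations on (site,
valid date, variable): forecast-days without an observation produce no
row. Forecast mean/SD are (μ, σ) for normal forecasts and the ensemble
mean and sample (m−1) SD for ensembles. Central-interval hit flags use
μ ± z·σ (normal) or empirical type-7 quantiles (ensemble), boundary
inclusive, so coverage is deterministic.

## Baselines

**DOY climatology.** Per (site, variable, day-of-year): mean and sample
(n−1) SD over the years observed strictly before the fitting cutoff
(the information rule). Sample rather than population SD because year
counts are small (3–7 in realistic records). Two fallbacks keep the
null model total: a DOY observed in a single year takes the
site/variable pooled within-DOY residual SD (or, for a single-year
record, the overall observation SD), and DOY 366 inherits DOY 365 when
never observed. The forecast for a valid date is N(μ_DOY, σ²_DOY) for
that date's day of year.

The description "one SD for the whole horizon" admits two readings;
both are implemented. The default varies σ per valid day's DOY; the
switch `constant_sigma_over_horizon` instead holds the first forecast
day's σ fixed across all 30 horizons. Neither is asserted as canonical.

**Persistence.** The last observation available under the latency rule,
at every horizon, with random-walk uncertainty σ_h = s₁√h where s₁ is
the sample SD of historical one-day differences. The √h growth is the
standard null for a last-observation-carried-forward model; when a
record has almost no consecutive-day pairs, s₁ is estimated from lagged
differences scaled by 1/√lag.

## Synthesis statistics

* **Relative skill** = CRPS(model) − CRPS(DOY), per forecast-day,
  negative when the model wins. Aggregations are equal-weight means
  over scored (site, issue date, horizon) rows within each group —
  sites are pooled, not averaged-then-pooled; the per-site grouping is
  provided as the alternative view, and a test documents that the two
  differ when sites are unbalanced.
* **Inclusion rules.** Horizon 16 is dropped first (its driver
  forecasts carried a processing artifact in the real challenge; only
  the exclusion rule is reproduced here). Then, per site/variable,
  models scoring fewer than 80% of evaluated days (unique observation
  days seen by any model) are dropped, with an audit table. The horizon
  dimension is not part of the denominator.
* **Reliability.** Proportion of observations inside the central 80%
  and 95% intervals per model × horizon, with an exact Clopper–Pearson
  95% binomial interval reported alongside. Classification is by sign
  of the deviation from the nominal level (underconfident above,
  overconfident below) with no sampling-error band — the interval is
  surfaced rather than hidden in the label.
* **Climatology divergence.** Per site × month, the focal year's median
  daily observation minus the pooled historical median, flagged beyond
  1 °C. This is the diagnostic that identifies site-years where a
  climatological null must fail.

## The synthetic challenge

The generator produces a world whose statistics match what the
synthesis assumes, not a hydrodynamic simulation (no stratification or
ice thermodynamics, no real weather-model grammar).

**Water truth.** Daily temperature = mean + amplitude ·
cos(2π(DOY − phase)/365.25) + stationary AR(1) anomaly (+ additive
monthly offsets in one focal year). With `air_coupling` set, the
anomaly and the offsets instead arrive through an exponential
heat-exchange filter (coefficient k/day) of the site's air-temperature
forcing, plus the lake's own AR(1): this makes the world dynamically
consistent with a process model driven by air temperature, which is
what gives process-class models genuine long-horizon information about
an anomalous year. Dissolved-oxygen truth is an anticorrelated
solubility-style transform of temperature (−0.25 mg L⁻¹ per °C around
the site mean) plus its own AR(1); only its statistical shape matters.

**Sensors.** 48 records/day at configured depths with additive Gaussian
noise, whole-day maintenance dropouts (Bernoulli), no data inside the
winter ice window, optional short-deployment start year, and
configurable fractions of QC-flagged and out-of-range spike records for
the QC stage to remove. Data latency defaults to 2 days — the
conservative end of the 2–3-day range a real sensor network exhibits.

**Pseudo-weather.** Per issue date, a 31-member ensemble out to 35
days. Member error is bias-free Gaussian with a saturating growth curve
sd(h) = sd_max(1 − e^(−h/τ)) (defaults sd_max = 3.5 °C, τ = 6 days,
roughly the shape of medium-range air-temperature error), smoothed
across horizons by an AR(ρ = 0.9) process so member trajectories are
realistic rather than white. The `dispersion` factor sets ensemble
spread relative to error SD (1 = calibrated; < 1 shares part of the
error across members; > 1 overdisperses). A "historic" product of
stacked 1-day-ahead values is emitted for model calibration.

**Model classes.** All stand-ins are stylized by class and labeled as
such; none reproduces a specific real submission.

* *process*: dT/dt = k(T_air − T_w), Euler-integrated daily from the
  last available observation, driven by historic values up to the issue
  date and the ensemble beyond it. k defaults to 0.15/day (a shallow
  lake's surface mixed layer).
* *empirical*: OLS on seasonal harmonics (optionally + air
  temperature), residual carried forward by a fitted AR(1).
* *ml*: the same machinery plus a lag-1 autoregressive term, iterated
  daily over the horizon — a stand-in for flexible autoregressive
  learners.
* *mme*: pools constituent members; normal constituents contribute 31
  equally spaced quantile members.
* *baseline*: delegates to the baselines module exactly (an equivalence
  the tests assert).

The five uncertainty sources map onto mechanics: driver → ecological
member i consumes weather member i (no resampling); parameter →
per-member parameter draws (lognormal for k, coefficient-covariance
normal for regressions); process → per-step additive noise; initial
condition → perturbed start state; observation → noise on emitted
values. At least one source must be enabled, mirroring the submission
requirement to include uncertainty.

**Information contract.** Forecasts issued on day t consult only
targets dated ≤ t − latency and weather issued ≤ t. All randomness
comes from substreams keyed by CRC-32 hashes of (site, model, variable,
issue date) under a single master seed, so generation is a pure
function of (config, seed), order-independent, and bit-identical under
perturbation of any post-cutoff observation (asserted by test).

## Shipped configuration and problem sizes

The example configuration uses seven lakes: two prairie lakes whose
focal year runs 1.5–3 °C warm in April–July, an ice-free warm pair, two
climatology-consistent north-temperate lakes, and one short-record
arctic lake; four history years; weekly issue dates through the focal
year; horizons 1–30; 31-member weather. These sizes give ≈7,300 scored
temperature forecast-days per model — enough that the leaderboard
ordering and site contrasts are stable across seeds — and a full run
completes in about two minutes on one core. Monte-Carlo checks use 10⁴
forecast-days (coverage, propriety) and 10⁵ members (estimator
consistency), sized so their sampling error is several times smaller
than the tolerance being asserted.

## Numerical choices and degenerate inputs

* Scores are computed in double precision; CSV output uses
  shortest-round-trip float formatting, and readers parse with
  round-trip precision, so write→read is bit-exact (the determinism
  manifest hashes files byte-wise).
* σ = 0 forecasts are scored as point forecasts, and their intervals
  have zero width (boundary inclusive, so an exact hit counts).
* Ensemble member indices must be 1-based and contiguous; duplicates
  are rejected at construction, making member counts unambiguous.
* Dates are calendar dates; time-of-day components are truncated
  (daily-mean evaluation). Horizon = valid date − issue date in days;
  horizon 1 is the day after issue.
* Empty groups raise rather than return silent zeros (empty history for
  a baseline, empty skill table, missing constituent sets for an MME).

## What passing tests do and do not show

The synthetic world has Gaussian noise, a single sinusoidal harmonic,
linear air–water coupling, and no regime shifts, sensor drift, or
depth structure. Tests passing here demonstrate that the scoring,
baseline, inclusion, aggregation, and reliability machinery is correct
and that the pipeline's qualitative contrasts (anomalous site-years
degrade climatology and reward dynamics-aware models) emerge for the
right reasons. They do not certify any real model's skill, nor that
real lakes satisfy these statistical assumptions.

## Known limitations

* The climatology-recovery acceptance check is a family-wise test over
  ~366 day-of-year bins; it asserts the calibrated quantity (≥99% of
  bins within 3 standard errors, max z < 5) rather than a pointwise
  3-SE bound, which a correct estimator would fail by multiplicity
  about half the time.
* Persistence uncertainty (√h random walk) is a modeling choice, not a
  fitted property of the synthetic world.
* The DO process is phenomenological; no metabolism or saturation
  ceiling is modeled.
* No significance testing of skill differences is performed; the
  synthesis reports means, counts, and binomial intervals only.
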