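"""Seeded synthetic forecast challenge: lakes, sensors, weather, models.

This module generates every ingredient of a forecast-challenge
experiment with a known, controllable statistical structure:

* **Lake truth** — a daily true state per site built as a sinusoidal
  seasonal cycle plus a stationary AR(1) anomaly, with optional
  additive monthly offsets in one focal year (a "site-year diverging
  from climatology"). Dissolved oxygen truth is derived from the
  temperature truth through an anticorrelated solubility-style slope
  plus its own AR(1) anomaly.
* **Sensor observations** — 48 records/day at configured depths with
  additive noise, winter ice-removal windows, random maintenance gaps,
  and a configurable fraction of QC-flagged or out-of-range records for
  the targets module to remove.
* **Pseudo-weather ensembles** — per issue date, an m-member air
  temperature forecast whose per-horizon error SD follows a nondecreasing
  growth curve, plus a "historic" product of stacked 1-day-ahead values.
* **Model forecasts** — stylized stand-ins for the submitted model
  classes (process-based heat exchange, seasonal/lag regressions,
  multimodel ensembles, baselines), each carrying a configurable subset
  of the five forecast-uncertainty sources: driver, parameter, process,
  initial condition, and observation.

All generators are pure functions of (config, seed): a single master
seed is expanded into independent substreams keyed by stable hashes of
(site, model, issue date, purpose), so outputs are reproducible and
insensitive to generation order. Models honour the information contract:
forecasts issued on day *t* use only targets dated at most
``t - latency`` and weather issued at most on *t*.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import fit_doy_climatology, forecast_doy, forecast_persistence
from .io_formats import FORECAST_COLUMNS, ForecastSet
from .targets import SENSOR_COLUMNS

__all__ = [
    "LakeConfig",
    "WeatherConfig",
    "UncertaintySpec",
    "ModelSpec",
    "WeatherForecasts",
    "simulate_lake_truth",
    "simulate_do_truth",
    "simulate_air_truth",
    "simulate_observations",
    "simulate_weather_forecasts",
    "generate_model_forecasts",
    "pool_mme",
]

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class LakeConfig:
    """Statistical description of one synthetic lake site.

    Temperature truth is ``mean + amplitude * cos(2*pi*(doy - phase_doy) /
    365.25)`` plus an AR(1) anomaly with coefficient ``ar1_phi`` and
    innovation SD ``ar1_sd``; in the focal year, ``monthly_offsets``
    (month -> additive degC) shift the truth away from climatology.
    ``ice_window`` is a (start, end) DOY interval — wrapping over the new
    year — during which the sensor is removed. ``latency_days`` is the
    delay before an observation becomes available to forecasters.
    Air temperature (the weather driver) shares the seasonal phase
    (shifted ``air_phase_lead`` days earlier) so that a heat-exchange
    model forced by air temperature is dynamically consistent with the
    water cycle.
    """

    site_id: str
    mean: float = 15.0
    amplitude: float = 10.0
    phase_doy: float = 200.0
    ar1_phi: float = 0.8
    ar1_sd: float = 0.5
    monthly_offsets: dict[int, float] = field(default_factory=dict)
    ice_window: tuple[int, int] | None = None
    gap_rate: float = 0.01
    obs_noise_sd: float = 0.1
    flag_rate: float = 0.01
    outlier_rate: float = 0.0
    latency_days: int = 2
    depths: tuple[float, ...] = (0.5,)
    first_year: int | None = None  # None: full record from challenge start
    # dissolved-oxygen process (anticorrelated solubility-style curve)
    do_mean: float = 9.0
    do_temp_slope: float = 0.25
    do_ar1_phi: float = 0.8
    do_ar1_sd: float = 0.15
    # air-temperature driver process
    air_amplitude_factor: float = 1.01
    air_phase_lead: float = 7.0
    air_ar1_phi: float = 0.7
    air_ar1_sd: float = 2.0
    air_offset_factor: float = 1.0
    #: when set, the water anomaly (and the focal-year offsets) are the
    #: exponential heat-exchange filter of the air forcing with this daily
    #: coefficient, plus the lake's own AR(1); None = purely additive truth
    air_coupling: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        for phi in (self.ar1_phi, self.do_ar1_phi, self.air_ar1_phi):
            if not 0.0 <= phi < 1.0:
                raise ValueError("AR(1) coefficient must satisfy 0 <= phi < 1")
        if self.latency_days < 0:
            raise ValueError("latency must be non-negative")


@dataclass
class WeatherConfig:
    """Pseudo-weather ensemble: member count, horizon, error growth.

    ``error_sd(h)`` is a saturating growth curve
    ``sd_max * (1 - exp(-h / timescale))`` unless an explicit
    nondecreasing per-horizon curve is supplied. ``dispersion`` is the
    ratio of ensemble spread to the true per-member error SD: 1 means
    calibrated, <1 overconfident, >1 underconfident. ``error_autocorr``
    smooths member error trajectories across horizons without changing
    their marginal SD.
    """

    n_members: int = 31
    max_horizon: int = 35
    sd_max: float = 3.5
    timescale: float = 6.0
    error_growth: tuple[float, ...] | None = None
    dispersion: float = 1.0
    error_autocorr: float = 0.9

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("weather ensemble needs at least 2 members")
        if self.error_growth is not None:
            curve = np.asarray(self.error_growth, dtype=float)
            if len(curve) < self.max_horizon:
                raise ValueError("error_growth must cover max_horizon entries")
            if np.any(np.diff(curve) < 0):
                raise ValueError("error SD must be nondecreasing in horizon")

    def error_sd(self, horizons: np.ndarray) -> np.ndarray:
        h = np.asarray(horizons, dtype=float)
        if self.error_growth is not None:
            return np.asarray(self.error_growth, dtype=float)[h.astype(int) - 1]
        return self.sd_max * (1.0 - np.exp(-h / self.timescale))


@dataclass
class UncertaintySpec:
    """Which of the five uncertainty sources a model carries, and how big.

    driver — one trajectory per weather ensemble member;
    parameter — model parameters drawn per member;
    process — additive noise accumulated per forecast step;
    initial_condition — perturbed start state per member;
    observation — noise added to the emitted values.
    At least one source must be enabled: every submission carries an
    uncertainty estimate.
    """

    driver: bool = False
    parameter: bool = False
    process: bool = False
    initial_condition: bool = False
    observation: bool = False
    parameter_sd: float = 0.15
    process_sd: float = 0.15
    initial_condition_sd: float = 0.25
    observation_sd: float = 0.1

    def __post_init__(self) -> None:
        if not any([self.driver, self.parameter, self.process,
                    self.initial_condition, self.observation]):
            raise ValueError("at least one uncertainty source must be enabled")

    def enabled(self) -> tuple[str, ...]:
        return tuple(
            name for name in ("driver", "parameter", "process", "initial_condition", "observation")
            if getattr(self, name)
        )


@dataclass
class ModelSpec:
    """A stylized stand-in for one submitted forecast model.

    ``model_class`` selects the mechanism: ``process`` integrates a
    one-parameter heat-exchange model dT/dt = k (T_air - T_w);
    ``empirical`` fits a seasonal-harmonic regression with an AR(1)
    residual; ``ml`` fits a lag-1 autoregression with seasonal terms,
    iterated over the horizon; ``mme`` pools the members of >= 2
    constituent models; ``baseline`` reproduces the baselines module
    exactly (``baseline_which`` in {doy, persistence}).
    """

    model_id: str
    model_class: str  # process | empirical | ml | mme | baseline
    uncertainty: UncertaintySpec = field(
        default_factory=lambda: UncertaintySpec(process=True)
    )
    covariates: tuple[str, ...] = ()  # subset of {"air_temperature"}
    variables: tuple[str, ...] = ("temperature",)
    n_members: int = 31
    k_exchange: float = 0.15
    baseline_which: str = "doy"
    constituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_class not in {"process", "empirical", "ml", "mme", "baseline"}:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.model_class == "mme" and len(self.constituents) < 2:
            raise ValueError("an MME must list at least 2 constituent model_ids")


@dataclass
class WeatherForecasts:
    """Driver forecasts for one site.

    ``ensemble``: long frame (issue_date, datetime, horizon, member,
    value). ``historic``: stacked 1-day-ahead values (date, value) — the
    estimate of observed conditions available for model calibration.
    """

    ensemble: pd.DataFrame = field(repr=False)
    historic: pd.DataFrame = field(repr=False)

    def member_matrix(self, issue_date) -> tuple[pd.DatetimeIndex, np.ndarray]:
        """(valid dates, members x horizons value matrix) for one issue date."""
        sub = self.ensemble[self.ensemble["issue_date"] == pd.Timestamp(issue_date)]
        if not len(sub):
            raise KeyError(f"no weather forecast issued on {issue_date}")
        wide = sub.pivot(index="member", columns="datetime", values="value").sort_index()
        return pd.DatetimeIndex(wide.columns), wide.to_numpy()


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def substream(seed: int, *tokens) -> np.random.Generator:
    """Independent random stream keyed by a master seed and stable tokens.

    Tokens (site ids, model ids, dates, purposes) are hashed with CRC-32,
    so streams do not depend on generation order or dict iteration.
    """
    ints = [zlib.crc32(str(t).encode("utf8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))


def _ar1(rng: np.random.Generator, n: int, phi: float, innov_sd: float) -> np.ndarray:
    """Stationary AR(1) path of length n (x0 from the stationary law)."""
    if innov_sd == 0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def _seasonal(dates: pd.DatetimeIndex, mean: float, amplitude: float, phase_doy: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy().astype(float)
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - phase_doy) / DAYS_PER_YEAR)


def _monthly_offsets(dates: pd.DatetimeIndex, offsets: dict[int, float], focal_year: int | None) -> np.ndarray:
    out = np.zeros(len(dates))
    if focal_year is None or not offsets:
        return out
    in_year = dates.year.to_numpy() == focal_year
    months = dates.month.to_numpy()
    for month, shift in offsets.items():
        out[in_year & (months == month)] += shift
    return out


# ---------------------------------------------------------------------------
# truth and observations
# ---------------------------------------------------------------------------


def _daily_index(start_year: int, n_years: int) -> pd.DatetimeIndex:
    if n_years < 1:
        raise ValueError("need at least one year")
    return pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")


def simulate_lake_truth(
    config: LakeConfig,
    start_year: int,
    n_years: int,
    focal_year: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily true surface water temperature for one site.

    Seasonal cycle + AR(1) anomaly + focal-year monthly offsets;
    deterministic for a given (config, seed). With ``air_coupling`` set,
    the anomaly (and the offsets) instead arrive through the
    heat-exchange filter of the site's air forcing — the same air
    realization :func:`simulate_air_truth` produces — plus the lake's own
    AR(1), so the synthetic world is dynamically consistent with a
    process model driven by air temperature.
    """
    dates = _daily_index(start_year, n_years)
    rng = substream(seed, config.site_id, "truth", "temperature")
    values = _seasonal(dates, config.mean, config.amplitude, config.phase_doy) + _ar1(
        rng, len(dates), config.ar1_phi, config.ar1_sd
    )
    if config.air_coupling:
        air_rng = substream(seed, config.site_id, "truth", "air")
        air_anom = _ar1(air_rng, len(dates), config.air_ar1_phi, config.air_ar1_sd)
        offsets = {m: v * config.air_offset_factor for m, v in config.monthly_offsets.items()}
        forcing = air_anom + _monthly_offsets(dates, offsets, focal_year)
        k = config.air_coupling
        coupled = np.empty(len(dates))
        state = forcing[0]  # start near equilibrium; transient decays in ~1/k days
        for t in range(len(dates)):
            state = state + k * (forcing[t] - state)
            coupled[t] = state
        values = values + coupled
    else:
        values = values + _monthly_offsets(dates, config.monthly_offsets, focal_year)
    return pd.DataFrame({"date": dates, "value": values})


def simulate_do_truth(temp_truth: pd.DataFrame, config: LakeConfig, seed: int = 0) -> pd.DataFrame:
    """Daily true dissolved oxygen derived from the temperature truth.

    An anticorrelated solubility-style curve — warmer water holds less
    oxygen — plus an independent AR(1) anomaly. Only the statistical
    shape matters for exercising the pipeline.
    """
    dates = pd.DatetimeIndex(temp_truth["date"])
    rng = substream(seed, config.site_id, "truth", "oxygen")
    values = (
        config.do_mean
        - config.do_temp_slope * (temp_truth["value"].to_numpy() - config.mean)
        + _ar1(rng, len(dates), config.do_ar1_phi, config.do_ar1_sd)
    )
    return pd.DataFrame({"date": dates, "value": values})


def simulate_air_truth(
    config: LakeConfig,
    start_year: int,
    n_years: int,
    focal_year: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily true air temperature (the weather driver) for one site.

    Shares the lake's seasonal cycle with a slightly larger amplitude and
    an earlier phase (air leads water), its own faster/noisier AR(1)
    anomaly, and the focal-year monthly offsets scaled by
    ``air_offset_factor`` — so a warm site-year is visible to models that
    use the air driver.
    """
    dates = _daily_index(start_year, n_years)
    rng = substream(seed, config.site_id, "truth", "air")
    offsets = {m: v * config.air_offset_factor for m, v in config.monthly_offsets.items()}
    values = (
        _seasonal(dates, config.mean, config.amplitude * config.air_amplitude_factor,
                  config.phase_doy - config.air_phase_lead)
        + _ar1(rng, len(dates), config.air_ar1_phi, config.air_ar1_sd)
        + _monthly_offsets(dates, offsets, focal_year)
    )
    return pd.DataFrame({"date": dates, "value": values})


def _in_ice_window(doys: np.ndarray, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return np.zeros(len(doys), dtype=bool)
    start, end = window
    if start <= end:
        return (doys >= start) & (doys <= end)
    return (doys >= start) | (doys <= end)


def simulate_observations(
    truth: pd.DataFrame,
    config: LakeConfig,
    seed: int = 0,
    variable: str = "temperature",
) -> pd.DataFrame:
    """30-min sensor records from a daily truth series.

    48 records per day at each configured depth with additive Gaussian
    noise. No records inside the ice window or on maintenance-gap days
    (whole-day Bernoulli dropout); records before ``config.first_year``
    are absent (short deployment records). A configurable fraction of
    records carry QC flags or out-of-range spike values for the targets
    module to remove.
    """
    dates = pd.DatetimeIndex(truth["date"])
    values = truth["value"].to_numpy()
    rng = substream(seed, config.site_id, "sensors", variable)

    doys = dates.dayofyear.to_numpy()
    keep_day = ~_in_ice_window(doys, config.ice_window)
    keep_day &= rng.random(len(dates)) >= config.gap_rate
    if config.first_year is not None:
        keep_day &= dates.year.to_numpy() >= config.first_year

    day_dates = dates[keep_day]
    day_values = values[keep_day]
    n_days = len(day_dates)
    n_per_day = 48 * len(config.depths)
    total = n_days * n_per_day
    if total == 0:
        return pd.DataFrame(columns=SENSOR_COLUMNS)

    slots = pd.to_timedelta(np.arange(48) * 30, unit="m")
    timestamps = np.repeat(day_dates.values, n_per_day) + np.tile(
        np.repeat(slots, len(config.depths)), n_days
    )
    depth = np.tile(np.asarray(config.depths), 48 * n_days)
    value = np.repeat(day_values, n_per_day) + rng.normal(0.0, config.obs_noise_sd, total)

    qc_flag = rng.random(total) < config.flag_rate
    spikes = rng.random(total) < config.outlier_rate
    value = np.where(spikes, 1000.0, value)

    return pd.DataFrame(
        {
            "site_id": config.site_id,
            "timestamp": timestamps,
            "depth": depth,
            "variable": variable,
            "value": value,
            "qc_flag": qc_flag,
        }
    )[SENSOR_COLUMNS]


# ---------------------------------------------------------------------------
# pseudo-weather
# ---------------------------------------------------------------------------


def _standardized_ar_path(rng: np.random.Generator, shape: tuple[int, ...], rho: float) -> np.ndarray:
    """AR path over the last axis with unit marginal SD at every step."""
    z = rng.standard_normal(shape)
    out = np.empty_like(z)
    out[..., 0] = z[..., 0]
    c = np.sqrt(1.0 - rho * rho)
    for h in range(1, shape[-1]):
        out[..., h] = rho * out[..., h - 1] + c * z[..., h]
    return out


def simulate_weather_forecasts(
    air_truth: pd.DataFrame,
    config: WeatherConfig,
    issue_dates,
    seed: int = 0,
    site_id: str = "site",
) -> WeatherForecasts:
    """Ensemble air-temperature forecasts plus the stacked historic product.

    Per issue date, each of the m members is the truth plus a bias-free
    Gaussian error whose per-horizon SD follows the growth curve; with
    ``dispersion < 1`` part of the error is shared across members so the
    ensemble spread is ``dispersion * error SD`` while each member keeps
    the full error SD; with ``dispersion > 1`` members are overdispersed.
    The historic product stacks 1-day-ahead values for every truth date.
    """
    truth = air_truth.set_index(pd.DatetimeIndex(air_truth["date"]))["value"]
    horizons = np.arange(1, config.max_horizon + 1)
    sd = config.error_sd(horizons)
    d = config.dispersion
    common_frac = np.sqrt(max(0.0, 1.0 - d * d)) if d <= 1.0 else 0.0
    member_frac = min(d, 1.0) if d <= 1.0 else d

    frames = []
    for issue in pd.DatetimeIndex(issue_dates):
        valid = issue + pd.to_timedelta(horizons, unit="D")
        if valid[-1] > truth.index[-1] or issue < truth.index[0]:
            raise ValueError(f"issue date {issue.date()} exceeds the truth span")
        base = truth.loc[valid].to_numpy()
        rng = substream(seed, site_id, "weather", issue.date().isoformat())
        z_common = _standardized_ar_path(rng, (1, len(horizons)), config.error_autocorr)
        z_member = _standardized_ar_path(
            rng, (config.n_members, len(horizons)), config.error_autocorr
        )
        err = sd * (common_frac * z_common + member_frac * z_member)
        values = base[None, :] + err
        frames.append(
            pd.DataFrame(
                {
                    "issue_date": np.repeat(issue, config.n_members * len(horizons)),
                    "datetime": np.tile(valid, config.n_members),
                    "horizon": np.tile(horizons, config.n_members),
                    "member": np.repeat(np.arange(1, config.n_members + 1), len(horizons)),
                    "value": values.ravel(),
                }
            )
        )
    ensemble = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["issue_date", "datetime", "horizon", "member", "value"]
    )

    rng_h = substream(seed, site_id, "weather", "historic")
    sd1 = float(config.error_sd(np.array([1]))[0])
    historic = pd.DataFrame(
        {
            "date": truth.index,
            "value": truth.to_numpy() + rng_h.normal(0.0, sd1, len(truth)),
        }
    )
    return WeatherForecasts(ensemble=ensemble, historic=historic)


# ---------------------------------------------------------------------------
# model forecast generation
# ---------------------------------------------------------------------------


def _ensemble_frame(model_id, issue, valid_dates, site_id, variable, values: np.ndarray) -> pd.DataFrame:
    """Long-format ensemble rows from a (members x horizons) value matrix."""
    n_mem, n_h = values.shape
    return pd.DataFrame(
        {
            "model_id": model_id,
            "reference_datetime": np.repeat(pd.Timestamp(issue), n_mem * n_h),
            "datetime": np.tile(valid_dates, n_mem),
            "site_id": site_id,
            "variable": variable,
            "family": "ensemble",
            "parameter": np.repeat(np.arange(1, n_mem + 1), n_h).astype(str),
            "prediction": values.ravel(),
        }
    )[FORECAST_COLUMNS]


def _air_paths(
    weather: WeatherForecasts,
    issue: pd.Timestamp,
    gap_dates: pd.DatetimeIndex,
    future_dates: pd.DatetimeIndex,
    n_members: int,
    per_member: bool,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """(members x days) air trajectories over gap + future dates.

    Gap days (after the last available observation, up to the issue date)
    come from the historic product; future days from the ensemble issued
    on the issue date — one trajectory per member when ``per_member``
    (driver uncertainty), otherwise the ensemble mean replicated.
    """
    hist = weather.historic.set_index(pd.DatetimeIndex(weather.historic["date"]))["value"]
    gap_vals = hist.loc[gap_dates].to_numpy() if len(gap_dates) else np.empty(0)
    valid, matrix = weather.member_matrix(issue)
    pos = valid.get_indexer(future_dates)
    if (pos < 0).any():
        raise ValueError("weather forecast does not cover the requested horizon")
    fut = matrix[:, pos]
    if per_member:
        if fut.shape[0] != n_members:
            raise ValueError("member count mismatch between model and weather ensemble")
        future_vals = fut
    else:
        future_vals = np.repeat(fut.mean(axis=0)[None, :], n_members, axis=0)
    gap = np.repeat(gap_vals[None, :], n_members, axis=0)
    return np.concatenate([gap, future_vals], axis=1)


def _forecast_process(
    spec: ModelSpec,
    avail: pd.DataFrame,
    weather: WeatherForecasts,
    issue: pd.Timestamp,
    valid_dates: pd.DatetimeIndex,
    rng: np.random.Generator,
) -> np.ndarray:
    """Heat-exchange model dT/dt = k (T_air - T_w), Euler-integrated daily."""
    if weather is None:
        raise ValueError("the heat-exchange model requires a weather driver")
    u = spec.uncertainty
    last = avail.sort_values("date").iloc[-1]
    t_last = pd.Timestamp(last["date"])
    T0 = float(last["observation"])
    n_mem = spec.n_members

    step_dates = pd.date_range(t_last + pd.Timedelta(days=1), valid_dates[-1], freq="D")
    gap_dates = step_dates[step_dates <= issue]
    future_dates = step_dates[step_dates > issue]
    air = _air_paths(weather, issue, gap_dates, future_dates, n_mem, u.driver, rng)

    k = np.full(n_mem, spec.k_exchange)
    if u.parameter:
        k = k * np.exp(rng.normal(0.0, u.parameter_sd, n_mem))
    T = np.full(n_mem, T0)
    if u.initial_condition:
        T = T + rng.normal(0.0, u.initial_condition_sd, n_mem)

    proc = rng.normal(0.0, u.process_sd, (n_mem, len(step_dates))) if u.process else None
    out = np.empty((n_mem, len(step_dates)))
    for i in range(len(step_dates)):
        T = T + k * (air[:, i] - T)
        if proc is not None:
            T = T + proc[:, i]
        out[:, i] = T
    keep = step_dates.get_indexer(valid_dates)
    values = out[:, keep]
    if u.observation:
        values = values + rng.normal(0.0, u.observation_sd, values.shape)
    return values


def _design_matrix(dates: pd.DatetimeIndex, air: np.ndarray | None, lagged: np.ndarray | None):
    doy = dates.dayofyear.to_numpy().astype(float)
    cols = [
        np.ones(len(dates)),
        np.sin(2 * np.pi * doy / DAYS_PER_YEAR),
        np.cos(2 * np.pi * doy / DAYS_PER_YEAR),
    ]
    if air is not None:
        cols.append(air)
    if lagged is not None:
        cols.append(lagged)
    return np.column_stack(cols)


def _fit_ols(X: np.ndarray, y: np.ndarray):
    """OLS coefficients, residuals, and coefficient covariance."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    return beta, resid, s2 * xtx_inv


def _perturbed_coefs(beta: np.ndarray, cov: np.ndarray, n: int, scale: float,
                     rng: np.random.Generator) -> np.ndarray:
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        L = np.diag(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    return beta[None, :] + scale * (rng.standard_normal((n, len(beta))) @ L.T)


def _forecast_regression(
    spec: ModelSpec,
    avail: pd.DataFrame,
    weather: WeatherForecasts | None,
    issue: pd.Timestamp,
    valid_dates: pd.DatetimeIndex,
    rng: np.random.Generator,
    use_lag: bool,
) -> np.ndarray:
    """Seasonal-harmonic regression ("empirical") or lag-1 form ("ml").

    The empirical form models y ~ harmonics (+ air), with an AR(1)
    residual carried from the last observation. The ml form adds a lag-1
    autoregressive term and is iterated daily over the horizon.
    """
    u = spec.uncertainty
    use_air = "air_temperature" in spec.covariates
    if (use_air or u.driver) and weather is None:
        raise ValueError("model requires a weather driver but none was supplied")
    avail = avail.sort_values("date")
    obs_dates = pd.DatetimeIndex(avail["date"])
    y = avail["observation"].to_numpy()
    n_mem = spec.n_members

    hist_air = None
    if use_air:
        hist = weather.historic.set_index(pd.DatetimeIndex(weather.historic["date"]))["value"]
        hist_air = hist.reindex(obs_dates).to_numpy()
        ok = ~np.isnan(hist_air)
        obs_dates, y, hist_air = obs_dates[ok], y[ok], hist_air[ok]

    if use_lag:
        lag_ok = (obs_dates[1:] - obs_dates[:-1]).days == 1
        X = _design_matrix(obs_dates[1:][lag_ok],
                           hist_air[1:][lag_ok] if use_air else None,
                           y[:-1][lag_ok])
        beta, resid, cov = _fit_ols(X, y[1:][lag_ok])
    else:
        X = _design_matrix(obs_dates, hist_air, None)
        beta, resid, cov = _fit_ols(X, y)

    if u.parameter:
        betas = _perturbed_coefs(beta, cov, n_mem, 1.0, rng)
    else:
        betas = np.repeat(beta[None, :], n_mem, axis=0)

    t_last = obs_dates[-1]
    step_dates = pd.date_range(t_last + pd.Timedelta(days=1), valid_dates[-1], freq="D")
    gap_dates = step_dates[step_dates <= issue]
    future_dates = step_dates[step_dates > issue]
    if use_air:
        air = _air_paths(weather, issue, gap_dates, future_dates, n_mem, u.driver, rng)
    else:
        air = None

    # residual AR(1) from consecutive-day residual pairs
    consec = (obs_dates[1:] - obs_dates[:-1]).days == 1
    if use_lag:
        phi_r, innov_sd = 0.0, float(np.sqrt(max(resid.var(), 1e-12)))
    else:
        r = resid
        if consec.sum() >= 3 and r[:-1][consec].std() > 0:
            phi_r = float(np.corrcoef(r[:-1][consec], r[1:][consec])[0, 1])
            phi_r = float(np.clip(phi_r, 0.0, 0.99))
        else:
            phi_r = 0.0
        innov_sd = float(r.std() * np.sqrt(max(1.0 - phi_r**2, 1e-6)))

    out = np.empty((n_mem, len(step_dates)))
    if use_lag:
        state = np.full(n_mem, y[-1])
        if u.initial_condition:
            state = state + rng.normal(0.0, u.initial_condition_sd, n_mem)
        proc = rng.normal(0.0, innov_sd, (n_mem, len(step_dates))) if u.process else None
        for i, d in enumerate(step_dates):
            doy = float(d.dayofyear)
            base = np.array([1.0, np.sin(2 * np.pi * doy / DAYS_PER_YEAR),
                             np.cos(2 * np.pi * doy / DAYS_PER_YEAR)])
            cols = [np.repeat(base[None, :], n_mem, axis=0)]
            if use_air:
                cols.append(air[:, i, None])
            cols.append(state[:, None])
            rows = np.concatenate(cols, axis=1)
            state = np.einsum("ij,ij->i", rows, betas)
            if proc is not None:
                state = state + proc[:, i]
            out[:, i] = state
    else:
        r0 = np.full(n_mem, float(resid[-1]))
        if u.initial_condition:
            r0 = r0 + rng.normal(0.0, u.initial_condition_sd, n_mem)
        proc = rng.normal(0.0, innov_sd, (n_mem, len(step_dates))) if u.process else None
        r = r0
        for i, d in enumerate(step_dates):
            r = phi_r * r
            if proc is not None:
                r = r + proc[:, i]
            doy = float(d.dayofyear)
            base = np.array([1.0, np.sin(2 * np.pi * doy / DAYS_PER_YEAR),
                             np.cos(2 * np.pi * doy / DAYS_PER_YEAR)])
            if use_air:
                rows = np.column_stack([np.repeat(base[None, :], n_mem, axis=0), air[:, i]])
            else:
                rows = np.repeat(base[None, :], n_mem, axis=0)
            out[:, i] = np.einsum("ij,ij->i", rows, betas) + r

    keep = step_dates.get_indexer(valid_dates)
    values = out[:, keep]
    if u.observation:
        values = values + rng.normal(0.0, u.observation_sd, values.shape)
    return values


def generate_model_forecasts(
    spec: ModelSpec,
    targets: pd.DataFrame,
    weather: dict[str, WeatherForecasts] | WeatherForecasts | None,
    issue_dates,
    seed: int = 0,
    horizons: range = range(1, 31),
    latency_days: int = 2,
    constituents: dict[str, ForecastSet] | None = None,
) -> ForecastSet:
    """Generate one model's forecast submissions over the issue dates.

    Honours the information contract: only targets dated at most
    ``issue - latency_days`` and weather issued on (or before) the issue
    date are consulted, so late ("retroactive") regeneration produces
    bit-identical forecasts. Uncertainty sources enabled in
    ``spec.uncertainty`` map onto generation mechanics (see
    :class:`UncertaintySpec`). Baseline specs delegate to the baselines
    module; MME specs pool the supplied constituent forecast sets.
    """
    if spec.model_class == "mme":
        if not constituents:
            raise ValueError("MME spec requires constituent forecast sets")
        missing = [m for m in spec.constituents if m not in constituents]
        if missing:
            raise ValueError(f"missing constituent forecast sets: {missing}")
        return pool_mme({m: constituents[m] for m in spec.constituents}, spec.model_id)

    if spec.uncertainty.driver and spec.model_class != "baseline" and weather is None:
        raise ValueError("spec requests driver uncertainty but no weather was supplied")

    targets = targets.copy()
    targets["date"] = pd.to_datetime(targets["date"])
    site_ids = sorted(targets["site_id"].unique())
    weather_by_site: dict[str, WeatherForecasts | None]
    if isinstance(weather, WeatherForecasts):
        if len(site_ids) != 1:
            raise ValueError("pass a site -> weather mapping for multi-site targets")
        weather_by_site = {site_ids[0]: weather}
    else:
        weather_by_site = dict(weather) if weather else {}

    h_list = list(horizons)
    frames: list[pd.DataFrame] = []
    for issue in pd.DatetimeIndex(issue_dates):
        cutoff = issue - pd.Timedelta(days=latency_days)
        avail_all = targets[targets["date"] <= cutoff]
        valid_dates = issue + pd.to_timedelta(h_list, unit="D")
        for site_id in site_ids:
            wx = weather_by_site.get(site_id)
            for variable in spec.variables:
                avail = avail_all[
                    (avail_all["site_id"] == site_id) & (avail_all["variable"] == variable)
                ]
                if not len(avail):
                    continue
                if spec.model_class == "baseline":
                    fs = _baseline_forecast(spec, avail, issue, h_list, site_id, variable,
                                            latency_days)
                    if fs is not None:
                        frames.append(fs)
                    continue
                rng = substream(seed, spec.model_id, site_id, variable,
                                issue.date().isoformat())
                if spec.model_class == "process":
                    values = _forecast_process(spec, avail, wx, issue, valid_dates, rng)
                else:
                    values = _forecast_regression(
                        spec, avail, wx, issue, valid_dates, rng,
                        use_lag=(spec.model_class == "ml"),
                    )
                frames.append(
                    _ensemble_frame(spec.model_id, issue, valid_dates, site_id, variable, values)
                )
    if not frames:
        return ForecastSet(pd.DataFrame(columns=FORECAST_COLUMNS))
    return ForecastSet(pd.concat(frames, ignore_index=True))


def _baseline_forecast(spec, avail, issue, h_list, site_id, variable, latency_days):
    hzs = range(min(h_list), max(h_list) + 1)
    try:
        if spec.baseline_which == "doy":
            clim = fit_doy_climatology(avail, as_of=issue)
            fs = forecast_doy(clim, issue, hzs, model_id=spec.model_id,
                              sites=[site_id], variables=[variable], skip_missing=True)
        else:
            fs = forecast_persistence(avail, issue, hzs, model_id=spec.model_id,
                                      latency_days=0)  # avail already latency-cut
    except ValueError:
        return None
    return fs.frame[FORECAST_COLUMNS]


def pool_mme(constituents: dict[str, ForecastSet], model_id: str,
             n_quantile_members: int = 31) -> ForecastSet:
    """Pool constituent forecasts into one multimodel ensemble.

    Ensemble constituents contribute their raw members; normal
    constituents contribute ``n_quantile_members`` equally spaced
    quantile members (plotting positions (i - 0.5)/n). Pooled members
    are renumbered contiguously per distribution key.
    """
    from scipy import stats as _stats

    parts = []
    for fs in constituents.values():
        df = fs.frame
        ens = df[df["family"] == "ensemble"]
        if len(ens):
            parts.append(ens[FORECAST_COLUMNS])
        normal = df[df["family"] == "normal"]
        if len(normal):
            wide = normal.pivot_table(
                index=["reference_datetime", "datetime", "site_id", "variable"],
                columns="parameter", values="prediction",
            ).reset_index()
            probs = (np.arange(1, n_quantile_members + 1) - 0.5) / n_quantile_members
            zq = _stats.norm.ppf(probs)
            n = len(wide)
            expanded = pd.DataFrame(
                {
                    "model_id": "constituent",
                    "reference_datetime": np.repeat(wide["reference_datetime"].values, len(zq)),
                    "datetime": np.repeat(wide["datetime"].values, len(zq)),
                    "site_id": np.repeat(wide["site_id"].values, len(zq)),
                    "variable": np.repeat(wide["variable"].values, len(zq)),
                    "family": "ensemble",
                    "parameter": "0",
                    "prediction": (
                        wide["mu"].to_numpy()[:, None] + wide["sigma"].to_numpy()[:, None] * zq
                    ).ravel(),
                }
            )
            parts.append(expanded[FORECAST_COLUMNS])
    pooled = pd.concat(parts, ignore_index=True)
    pooled["model_id"] = model_id
    pooled["family"] = "ensemble"
    key = ["reference_datetime", "datetime", "site_id", "variable"]
    pooled = pooled.sort_values(key + ["prediction"], kind="stable")
    pooled["parameter"] = (pooled.groupby(key).cumcount() + 1).astype(str)
    return ForecastSet(pooled.reset_index(drop=True))
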