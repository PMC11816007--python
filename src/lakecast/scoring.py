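"""Continuous ranked probability score (CRPS) and per-day score tables.

The CRPS of a forecast with CDF :math:`F` against an observation
:math:`y_\\mathrm{obs}` is

.. math::

    \\mathrm{CRPS}(F, y_\\mathrm{obs})
      = \\int \\bigl(F(y) - H(y - y_\\mathrm{obs})\\bigr)^2 \\, dy,

where :math:`H` is the Heaviside step function. It generalizes absolute
error to probabilistic forecasts, is expressed in the units of the
forecast variable, and is optimal (zero) for a point mass on the
observation. Two estimators are provided, matching the two supported
forecast families:

* :func:`crps_normal` — the closed form for a normal predictive
  distribution;
* :func:`crps_ensemble` — the empirical-CDF ("NRG") estimator for a
  finite ensemble, with the bias-corrected "fair" variant behind a flag.

:func:`score_forecasts` joins a forecast set to observations and produces
the per-forecast-day score table consumed by the evaluation module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DISTRIBUTION_KEY, ForecastSet

__all__ = ["crps_normal", "crps_ensemble", "score_forecasts", "SCORE_COLUMNS"]

_SQRT_PI = np.sqrt(np.pi)

SCORE_COLUMNS = [
    "model_id",
    "site_id",
    "variable",
    "reference_datetime",
    "datetime",
    "horizon",
    "crps",
    "forecast_mean",
    "forecast_sd",
    "abs_bias",
    "in_80_ci",
    "in_95_ci",
    "observation",
]


def crps_normal(mu, sigma, y):
    """CRPS of a normal forecast N(mu, sigma^2) against observation ``y``.

    Closed form (Gneiting & Raftery):

    .. math::

        \\mathrm{CRPS} = \\sigma \\left[ z(2\\Phi(z) - 1) + 2\\varphi(z)
            - \\pi^{-1/2} \\right], \\qquad z = (y - \\mu)/\\sigma.

    ``sigma = 0`` degenerates to the absolute error ``|mu - y|``.
    Vectorized over numpy-broadcastable inputs.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (y - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    out = sigma * (z * (2.0 * stats.norm.cdf(z) - 1.0) + 2.0 * stats.norm.pdf(z) - 1.0 / _SQRT_PI)
    out = np.where(sigma == 0, np.abs(mu - y), out)
    return out if out.ndim else float(out)


def crps_ensemble(members, y, fair: bool = False) -> float:
    """CRPS of a finite-ensemble forecast against observation ``y``.

    Empirical-CDF estimator over members :math:`x_1..x_m`:

    .. math::

        \\mathrm{CRPS} = \\frac{1}{m} \\sum_i |x_i - y|
           - \\frac{1}{2 m^2} \\sum_i \\sum_j |x_i - x_j|.

    With ``fair=True`` the pairwise term is divided by ``2 m (m-1)``
    instead, giving an unbiased estimate of the CRPS of the underlying
    distribution the members are drawn from.
    """
    x = np.sort(np.asarray(members, dtype=float))
    m = x.size
    if m == 0:
        raise ValueError("ensemble must have at least one member")
    term1 = np.mean(np.abs(x - y))
    if m == 1:
        return float(term1)
    # sum_{i,j} |x_i - x_j| = 2 * sum_i (2i - m + 1) x_(i)  (0-based sorted)
    i = np.arange(m)
    pairwise = 2.0 * np.sum((2 * i - m + 1) * x)
    denom = m * (m - 1) if fair else m * m
    return float(term1 - pairwise / (2.0 * denom))


def _ensemble_group_scores(values: np.ndarray, y: float, levels, fair: bool):
    """Scores for one ensemble: crps, mean, sample sd, CI-hit flags."""
    crps = crps_ensemble(values, y, fair=fair)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    hits = []
    for level in levels:
        lo, hi = np.quantile(values, [(1 - level) / 2, (1 + level) / 2])
        hits.append(bool(lo <= y <= hi))
    return crps, mean, sd, hits


def score_forecasts(
    forecasts: ForecastSet,
    targets: pd.DataFrame,
    levels: tuple[float, float] = (0.80, 0.95),
    fair: bool = False,
) -> pd.DataFrame:
    """Join forecasts to observations and score every forecast-day.

    Inner join on (site, valid date, variable): forecast-days without an
    observation produce no row. CRPS is dispatched by family; forecast
    mean/sd are (mu, sigma) for the normal family and the ensemble mean
    and sample (m-1) SD for the ensemble family. Central-interval hit
    flags use ``mu ± z·sigma`` for normal forecasts and empirical
    (linear-interpolation) quantiles for ensembles, boundary inclusive.

    Returns a score table with columns :data:`SCORE_COLUMNS`.
    """
    df = forecasts.frame
    obs = targets.rename(columns={"date": "datetime"})
    merged = df.merge(
        obs[["site_id", "datetime", "variable", "observation"]],
        on=["site_id", "datetime", "variable"],
        how="inner",
    )
    if not len(merged):
        return pd.DataFrame(columns=SCORE_COLUMNS)

    out_frames = []
    z = {level: stats.norm.ppf((1 + level) / 2) for level in levels}

    normal = merged[merged["family"] == "normal"]
    if len(normal):
        wide = normal.pivot_table(
            index=DISTRIBUTION_KEY + ["horizon", "observation"],
            columns="parameter",
            values="prediction",
        ).reset_index()
        mu = wide["mu"].to_numpy()
        sigma = wide["sigma"].to_numpy()
        y = wide["observation"].to_numpy()
        rows = wide[DISTRIBUTION_KEY + ["horizon", "observation"]].copy()
        rows["crps"] = crps_normal(mu, sigma, y)
        rows["forecast_mean"] = mu
        rows["forecast_sd"] = sigma
        rows["abs_bias"] = np.abs(mu - y)
        for level, col in zip(levels, ("in_80_ci", "in_95_ci")):
            half = z[level] * sigma
            rows[col] = (mu - half <= y) & (y <= mu + half)
        out_frames.append(rows)

    ens = merged[merged["family"] == "ensemble"]
    if len(ens):
        key_cols = DISTRIBUTION_KEY + ["horizon", "observation"]
        ens = ens.sort_values(key_cols)
        records = []
        for key, grp in ens.groupby(key_cols, sort=False):
            values = grp["prediction"].to_numpy()
            y_obs = key[-1]
            crps, mean, sd, hits = _ensemble_group_scores(values, y_obs, levels, fair)
            records.append((*key, crps, mean, sd, np.abs(mean - y_obs), *hits))
        rows = pd.DataFrame(
            records,
            columns=key_cols
            + ["crps", "forecast_mean", "forecast_sd", "abs_bias", "in_80_ci", "in_95_ci"],
        )
        out_frames.append(rows)

    out = pd.concat(out_frames, ignore_index=True)
    out = out[SCORE_COLUMNS].sort_values(
        ["model_id", "site_id", "variable", "reference_datetime", "horizon"]
    )
    return out.reset_index(drop=True)
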