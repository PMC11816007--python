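"""Null forecast models: day-of-year climatology and persistence.

The day-of-year (DOY) climatology forecasts each future date with the
historical mean for that calendar day, with normal uncertainty given by
the across-year SD of the same calendar day. It encodes "dynamics follow
the mean seasonal cycle" and is the reference model against which
relative skill is measured.

Persistence forecasts every horizon with the last available observation,
with random-walk uncertainty growing as sqrt(horizon).

Both emit standard normal-family :class:`~lakecast.io_formats.ForecastSet`
objects scoreable like any submission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FORECAST_COLUMNS, ForecastSet

__all__ = [
    "DOYClimatology",
    "fit_doy_climatology",
    "forecast_doy",
    "forecast_persistence",
]


@dataclass
class DOYClimatology:
    """Per-(site, variable, day-of-year) historical mean and SD.

    ``table`` has columns site_id, variable, doy, mu, sigma, n; ``as_of``
    records the information cutoff used when fitting (observations dated
    on or after it were never seen).
    """

    table: pd.DataFrame = field(repr=False)
    as_of: pd.Timestamp

    def lookup(
        self, site_id: str, variable: str, doys: np.ndarray, skip_missing: bool = False
    ) -> pd.DataFrame:
        sub = self.table[
            (self.table["site_id"] == site_id) & (self.table["variable"] == variable)
        ].set_index("doy")
        missing = [int(d) for d in doys if d not in sub.index]
        if missing and not skip_missing:
            raise KeyError(
                f"no climatology entry for {site_id}/{variable} DOY(s) {sorted(set(missing))}"
            )
        doys = np.asarray([d for d in doys if d not in missing])
        return sub.loc[doys, ["mu", "sigma", "n"]].reset_index()


def fit_doy_climatology(targets: pd.DataFrame, as_of) -> DOYClimatology:
    """Fit per-DOY mean and across-year sample SD from historical targets.

    Uses only observations dated strictly before ``as_of`` (information
    rule). For each (site, variable, DOY): ``mu`` is the mean over the
    available years, ``sigma`` the sample (n-1) SD. DOYs observed in a
    single year fall back to the site/variable pooled residual SD (the
    pooled within-DOY SD over multi-year DOYs); DOYs never observed are
    absent. DOY 366 inherits the DOY-365 entry when itself unobserved, so
    leap-year forecasting never hits an empty bin.
    """
    as_of = pd.Timestamp(as_of)
    hist = targets[pd.to_datetime(targets["date"]) < as_of].copy()
    if not len(hist):
        raise ValueError("no target observations before as_of; cannot fit climatology")
    hist["date"] = pd.to_datetime(hist["date"])
    hist["doy"] = hist["date"].dt.dayofyear

    grouped = hist.groupby(["site_id", "variable", "doy"])["observation"].agg(
        mu="mean", sigma=lambda v: v.std(ddof=1), n="count"
    )
    table = grouped.reset_index()

    # pooled residual SD per site/variable from multi-year DOYs; a site
    # with a single year of record falls back to its overall observation SD
    overall = hist.groupby(["site_id", "variable"])["observation"].std().fillna(0.0)

    def _pooled(sub: pd.DataFrame) -> float:
        multi = sub[sub["n"] > 1]
        if len(multi):
            dof = (multi["n"] - 1).sum()
            return float(np.sqrt((multi["sigma"] ** 2 * (multi["n"] - 1)).sum() / dof))
        return float("nan")

    pooled = (
        table.groupby(["site_id", "variable"])
        .apply(_pooled, include_groups=False)
        .fillna(overall)
        .rename("pooled_sd")
        .reset_index()
    )
    table = table.merge(pooled, on=["site_id", "variable"])
    table["sigma"] = np.where(table["n"] > 1, table["sigma"], table["pooled_sd"])
    table = table.drop(columns="pooled_sd")

    # leap-day fallback: pool DOY 366 with 365 where absent
    has366 = set(map(tuple, table.loc[table["doy"] == 366, ["site_id", "variable"]].values))
    fill = table[
        (table["doy"] == 365)
        & ~table.apply(lambda r: (r["site_id"], r["variable"]) in has366, axis=1)
    ].copy()
    if len(fill):
        fill["doy"] = 366
        table = pd.concat([table, fill], ignore_index=True)

    table = table.sort_values(["site_id", "variable", "doy"]).reset_index(drop=True)
    return DOYClimatology(table=table, as_of=as_of)


def _records(model_id, reference_date, valid_dates, site_id, variable, mus, sigmas):
    n = len(valid_dates)
    frame = pd.DataFrame(
        {
            "model_id": np.repeat(model_id, 2 * n),
            "reference_datetime": np.repeat(pd.Timestamp(reference_date), 2 * n),
            "datetime": np.tile(valid_dates, 2),
            "site_id": np.repeat(site_id, 2 * n),
            "variable": np.repeat(variable, 2 * n),
            "family": np.repeat("normal", 2 * n),
            "parameter": np.repeat(["mu", "sigma"], n),
            "prediction": np.concatenate([mus, sigmas]),
        }
    )
    return frame[FORECAST_COLUMNS]


def forecast_doy(
    clim: DOYClimatology,
    reference_date,
    horizons: range = range(1, 31),
    model_id: str = "climatology",
    sites: list[str] | None = None,
    variables: list[str] | None = None,
    constant_sigma_over_horizon: bool = False,
    skip_missing: bool = False,
) -> ForecastSet:
    """Issue DOY-climatology forecasts for the given horizons.

    Each valid date's forecast is N(mu_DOY, sigma_DOY^2) for that date's
    day of year; the year boundary is handled by the calendar itself.
    With ``constant_sigma_over_horizon`` the SD of the first forecast day
    is held fixed across all horizons (an alternative reading of "one SD
    for the whole horizon"); the default varies sigma per valid day.

    Raises ``KeyError`` naming the DOY if the climatology lacks an entry,
    unless ``skip_missing`` — then never-observed DOYs (e.g., inside a
    winter ice window) are silently left unforecast.
    """
    reference_date = pd.Timestamp(reference_date)
    valid_dates = pd.DatetimeIndex([reference_date + pd.Timedelta(days=h) for h in horizons])
    all_doys = valid_dates.dayofyear.to_numpy()
    pairs = clim.table[["site_id", "variable"]].drop_duplicates().itertuples(index=False)
    frames = []
    for site_id, variable in pairs:
        if sites is not None and site_id not in sites:
            continue
        if variables is not None and variable not in variables:
            continue
        entries = clim.lookup(site_id, variable, all_doys, skip_missing=skip_missing)
        if not len(entries):
            continue
        kept = valid_dates[np.isin(all_doys, entries["doy"].to_numpy())]
        sigmas = entries["sigma"].to_numpy().copy()
        if constant_sigma_over_horizon:
            sigmas[:] = sigmas[0]
        frames.append(
            _records(model_id, reference_date, kept, site_id, variable,
                     entries["mu"].to_numpy(), sigmas)
        )
    if not frames:
        raise ValueError("climatology has no (site, variable) entries to forecast")
    return ForecastSet(pd.concat(frames, ignore_index=True))


def forecast_persistence(
    targets: pd.DataFrame,
    reference_date,
    horizons: range = range(1, 31),
    model_id: str = "persistence",
    latency_days: int = 0,
) -> ForecastSet:
    """Issue persistence forecasts: last available observation at all horizons.

    The "last" observation respects the data-latency rule: only targets
    dated at most ``reference_date - latency_days`` are visible. The
    forecast mean is constant across horizons; uncertainty follows a
    random walk, ``sigma_h = s1 * sqrt(h)`` with ``s1`` the sample SD of
    historical one-day differences (when fewer than two consecutive-day
    pairs exist, ``s1`` is estimated from lagged differences scaled by
    ``1/sqrt(lag)``).
    """
    reference_date = pd.Timestamp(reference_date)
    cutoff = reference_date - pd.Timedelta(days=latency_days)
    hist = targets[pd.to_datetime(targets["date"]) <= cutoff].copy()
    if not len(hist):
        raise ValueError("no observation available before the reference date")
    hist["date"] = pd.to_datetime(hist["date"])
    valid_dates = pd.DatetimeIndex([reference_date + pd.Timedelta(days=h) for h in horizons])
    h_arr = np.asarray(list(horizons), dtype=float)

    frames = []
    for (site_id, variable), grp in hist.groupby(["site_id", "variable"]):
        grp = grp.sort_values("date")
        last = float(grp["observation"].iloc[-1])
        obs = grp["observation"].to_numpy()
        lags = grp["date"].diff().dt.days.to_numpy()[1:]
        diffs = np.diff(obs)
        one_day = diffs[lags == 1]
        if one_day.size >= 2:
            s1 = float(np.std(one_day, ddof=1))
        elif diffs.size >= 2:
            s1 = float(np.std(diffs / np.sqrt(lags), ddof=1))
        else:
            s1 = 0.0
        mus = np.full(len(h_arr), last)
        sigmas = s1 * np.sqrt(h_arr)
        frames.append(_records(model_id, reference_date, valid_dates, site_id, variable, mus, sigmas))
    return ForecastSet(pd.concat(frames, ignore_index=True))
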