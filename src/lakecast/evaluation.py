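"""Synthesis statistics: relative skill, inclusion rules, reliability.

Relative forecast skill is the per-forecast-day difference

    crps_skill = crps(model) - crps(reference)

with the reference being the day-of-year climatology. Negative values
mean the model beat the reference (the sign convention used throughout:
skill is reported as an error difference, so lower is better).

The module also implements the synthesis filters and summaries applied
before comparing models: dropping a corrupted horizon, requiring models
to have scored a minimum fraction of evaluated days, aggregating skill
over dates/horizons/sites, confidence-interval reliability (coverage),
bias and spread by horizon, and the divergence of a focal year from the
historical monthly climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ForecastSet
from .scoring import score_forecasts

__all__ = [
    "SkillResult",
    "InclusionResult",
    "compute_skill",
    "apply_inclusion_criteria",
    "aggregate_skill",
    "interval_coverage",
    "bias_and_spread",
    "climatology_divergence",
]

_JOIN_KEY = ["site_id", "variable", "reference_datetime", "datetime"]


@dataclass
class SkillResult:
    """Skill table plus an audit count of rows lacking a baseline score."""

    table: pd.DataFrame = field(repr=False)
    n_dropped: int = 0
    baseline_id: str = "climatology"


def compute_skill(
    scores: pd.DataFrame,
    baseline_scores: pd.DataFrame,
    baseline_id: str | None = None,
) -> SkillResult:
    """Per-row CRPS difference against the reference model.

    Rows of ``scores`` are matched to ``baseline_scores`` on
    (site, issue date, valid date, variable); unmatched rows are dropped
    and counted in the result. Antisymmetric: skilling A against B
    negates skilling B against A row-wise.
    """
    if baseline_id is None:
        ids = baseline_scores["model_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                "baseline_scores contains multiple models; pass baseline_id explicitly"
            )
        baseline_id = str(ids[0])
    base = baseline_scores[baseline_scores["model_id"] == baseline_id]
    if not len(base):
        raise ValueError(f"baseline model {baseline_id!r} absent from baseline scores")
    base = base[_JOIN_KEY + ["crps"]].rename(columns={"crps": "baseline_crps"})
    merged = scores.merge(base, on=_JOIN_KEY, how="left")
    n_dropped = int(merged["baseline_crps"].isna().sum())
    merged = merged.dropna(subset=["baseline_crps"]).copy()
    merged["crps_skill"] = merged["crps"] - merged["baseline_crps"]
    merged["baseline_id"] = baseline_id
    return SkillResult(table=merged.reset_index(drop=True), n_dropped=n_dropped,
                       baseline_id=baseline_id)


@dataclass
class InclusionResult:
    """Filtered score table plus the audit of what was removed."""

    table: pd.DataFrame = field(repr=False)
    dropped_models: pd.DataFrame = field(repr=False)
    excluded_horizons: frozenset[int] = frozenset()


def apply_inclusion_criteria(
    scores: pd.DataFrame,
    min_fraction: float = 0.8,
    excluded_horizons: set[int] = frozenset({16}),
) -> InclusionResult:
    """Apply the synthesis inclusion rules to a score table.

    First drops all rows at the excluded horizons (by default horizon 16,
    whose driver forecasts carried a processing artifact). Then, per
    (site, variable), drops models whose count of scored days is below
    ``min_fraction`` of the evaluated days — days with observations —
    seen by any model at that site/variable. The horizon dimension is not
    part of the denominator.

    Returns the filtered table and an audit frame of dropped
    (model, site, variable) combinations with their coverage fractions.
    """
    kept = scores[~scores["horizon"].isin(excluded_horizons)].copy()
    denom = (
        kept.groupby(["site_id", "variable"])["datetime"]
        .nunique()
        .rename("n_evaluated_days")
        .reset_index()
    )
    per_model = (
        kept.groupby(["model_id", "site_id", "variable"])["datetime"]
        .nunique()
        .rename("n_scored_days")
        .reset_index()
        .merge(denom, on=["site_id", "variable"])
    )
    per_model["fraction"] = per_model["n_scored_days"] / per_model["n_evaluated_days"]
    dropped = per_model[per_model["fraction"] < min_fraction].reset_index(drop=True)
    if len(dropped):
        drop_keys = set(map(tuple, dropped[["model_id", "site_id", "variable"]].values))
        mask = [
            (m, s, v) in drop_keys
            for m, s, v in zip(kept["model_id"], kept["site_id"], kept["variable"])
        ]
        kept = kept[~np.asarray(mask)]
    return InclusionResult(
        table=kept.reset_index(drop=True),
        dropped_models=dropped,
        excluded_horizons=frozenset(excluded_horizons),
    )


_GROUP_COLS = {"model": "model_id", "horizon": "horizon", "site": "site_id",
               "month": "month", "variable": "variable"}


def aggregate_skill(skills: pd.DataFrame, by=("model",)) -> pd.DataFrame:
    """Mean skill (and CRPS, absolute bias, spread) over grouped rows.

    ``by`` is a subset of {model, horizon, site, month, variable}. Every
    scored (site, issue date, horizon) row carries equal weight within a
    group — sites are pooled, not first averaged — and the group size
    ``n`` is reported. Note the arithmetic consequence: the pooled mean
    equals the mean of per-site means only when sites contribute equal
    row counts.
    """
    if not len(skills):
        raise ValueError("empty skill table")
    df = skills.copy()
    if "month" in by:
        df["month"] = pd.to_datetime(df["datetime"]).dt.month
    cols = [_GROUP_COLS[b] for b in by]
    value_cols = [c for c in ("crps_skill", "crps", "abs_bias", "forecast_sd") if c in df]
    agg = df.groupby(cols, sort=True)[value_cols].mean()
    agg["n"] = df.groupby(cols, sort=True).size()
    return agg.reset_index()


def interval_coverage(
    forecasts: ForecastSet | pd.DataFrame,
    targets: pd.DataFrame | None = None,
    levels: tuple[float, ...] = (0.80, 0.95),
) -> pd.DataFrame:
    """Reliability of central confidence intervals per model and horizon.

    Accepts either a forecast set plus targets (scored internally) or a
    pre-computed score table. For each model, horizon and nominal level
    the proportion of observations falling inside the central interval is
    reported with an exact (Clopper-Pearson) 95% binomial interval and a
    classification: ``underconfident`` when the proportion exceeds the
    nominal level (intervals too wide), ``overconfident`` below it.
    """
    if isinstance(forecasts, ForecastSet):
        if targets is None:
            raise ValueError("targets required when passing a ForecastSet")
        scores = score_forecasts(forecasts, targets, levels=tuple(levels[:2]))
    else:
        scores = forecasts
    col_for = {0.80: "in_80_ci", 0.95: "in_95_ci"}
    records = []
    for (model_id, horizon), grp in scores.groupby(["model_id", "horizon"]):
        for level in levels:
            col = col_for[round(level, 2)]
            n = len(grp)
            k = int(grp[col].sum())
            prop = k / n
            ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95)
            if prop > level:
                label = "underconfident"
            elif prop < level:
                label = "overconfident"
            else:
                label = "calibrated"
            records.append(
                (model_id, horizon, level, n, prop, ci.low, ci.high, label)
            )
    return pd.DataFrame(
        records,
        columns=["model_id", "horizon", "level", "n_evaluated", "proportion_in_ci",
                 "ci_low", "ci_high", "classification"],
    )


def bias_and_spread(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean forecast SD (spread) and mean absolute bias per model and horizon."""
    if not len(scores):
        raise ValueError("empty score table")
    agg = (
        scores.groupby(["model_id", "horizon"])[["forecast_sd", "abs_bias"]]
        .mean()
        .rename(columns={"forecast_sd": "mean_sd", "abs_bias": "mean_abs_bias"})
    )
    agg["n"] = scores.groupby(["model_id", "horizon"]).size()
    return agg.reset_index()


def climatology_divergence(
    targets: pd.DataFrame,
    focal_year: int,
    historical_years: list[int] | None = None,
    variable: str = "temperature",
    flag_threshold: float = 1.0,
) -> pd.DataFrame:
    """Monthly median divergence of a focal year from historical conditions.

    Per site and month: median of the focal year's daily observations
    minus the median of the pooled historical daily observations. Months
    lacking data in either period are absent. ``exceeds_threshold`` flags
    |delta| beyond ``flag_threshold`` (1 °C by default) — the shading
    convention used to mark site-years diverging from climatology.
    """
    df = targets[targets["variable"] == variable].copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    focal = df[df["year"] == focal_year]
    if historical_years is None:
        hist = df[df["year"] < focal_year]
    else:
        hist = df[df["year"].isin(historical_years)]
    if not len(hist):
        raise ValueError("no historical observations to compare against")
    fm = focal.groupby(["site_id", "month"])["observation"].median().rename("focal_median")
    hm = hist.groupby(["site_id", "month"])["observation"].median().rename("historical_median")
    out = pd.concat([fm, hm], axis=1, join="inner").reset_index()
    out["delta"] = out["focal_median"] - out["historical_median"]
    out["exceeds_threshold"] = out["delta"].abs() > flag_threshold
    return out.sort_values(["site_id", "month"]).reset_index(drop=True)
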