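"""Standardized forecast-submission and target-table formats.

Forecast submissions follow a long-format table with one row per
(model, issue date, valid date, site, variable, parameter) combination.
Two distribution families are supported:

* ``normal`` — two rows per forecast distribution, ``parameter`` equal to
  ``"mu"`` and ``"sigma"``, carrying the mean and standard deviation of a
  normally distributed forecast.
* ``ensemble`` — one row per ensemble member, ``parameter`` equal to the
  1-based member index, carrying that member's predicted value.

Targets (the evaluation truth) are daily surface-mean observations keyed by
(site, date, variable). All dates are calendar dates: any time-of-day
component in input files is truncated, because the challenge evaluates
daily means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FORECAST_COLUMNS",
    "TARGET_COLUMNS",
    "FormatError",
    "ForecastValidationError",
    "ForecastSet",
    "ValidationReport",
    "read_forecast_file",
    "write_forecast_file",
    "read_target_file",
    "write_target_file",
    "validate_forecast",
]

#: Column order of the standardized forecast CSV.
FORECAST_COLUMNS = [
    "model_id",
    "reference_datetime",
    "datetime",
    "site_id",
    "variable",
    "family",
    "parameter",
    "prediction",
]

#: Column order of the standardized target CSV.
TARGET_COLUMNS = ["site_id", "date", "variable", "observation"]

#: Recognised forecast variables and their units.
VARIABLES = {"temperature": "degC", "oxygen": "mg/L"}

FAMILIES = {"normal", "ensemble"}

#: Key identifying one forecast distribution.
DISTRIBUTION_KEY = ["model_id", "reference_datetime", "datetime", "site_id", "variable"]


class FormatError(ValueError):
    """A file does not conform to the standardized schema."""


class ForecastValidationError(ValueError):
    """A forecast table violates a structural invariant."""


def _as_date(series: pd.Series) -> pd.Series:
    """Parse to datetime64 and truncate to calendar date."""
    out = pd.to_datetime(series, format="ISO8601")
    return out.dt.normalize()


@dataclass
class ForecastSet:
    """A collection of probabilistic forecasts in the standardized long format.

    Wraps a :class:`pandas.DataFrame` with the columns of
    :data:`FORECAST_COLUMNS` plus a derived integer ``horizon`` column
    (days between issue and valid date). Construction validates the
    structural invariants of the format; a ``ForecastSet`` is therefore
    always well formed.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in FORECAST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df["reference_datetime"] = _as_date(df["reference_datetime"])
        df["datetime"] = _as_date(df["datetime"])
        df["prediction"] = df["prediction"].astype(float)
        df["parameter"] = df["parameter"].astype(str)
        df["horizon"] = (df["datetime"] - df["reference_datetime"]).dt.days
        df = df[FORECAST_COLUMNS + ["horizon"]].reset_index(drop=True)
        self.frame = df
        if len(df):
            self._validate()

    # -- structural invariants -------------------------------------------

    def _validate(self) -> None:
        problems = structural_violations(self.frame)
        if problems:
            key, probs = next(iter(problems.items()))
            raise ForecastValidationError(f"{key}: {probs[0]}")

    # -- convenience -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ForecastSet):
            return NotImplemented
        a = self.frame.sort_values(FORECAST_COLUMNS).reset_index(drop=True)
        b = other.frame.sort_values(FORECAST_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    @property
    def horizons(self) -> np.ndarray:
        return np.sort(self.frame["horizon"].unique())

    def member_count(self, *key_values) -> int:
        """Number of ensemble members for one distribution key."""
        df = self.frame
        mask = np.ones(len(df), dtype=bool)
        for col, val in zip(DISTRIBUTION_KEY, key_values):
            mask &= df[col] == val
        return int(mask.sum())

    @staticmethod
    def concat(sets: list["ForecastSet"]) -> "ForecastSet":
        frames = [s.frame[FORECAST_COLUMNS] for s in sets if len(s)]
        if not frames:
            return ForecastSet(pd.DataFrame(columns=FORECAST_COLUMNS))
        return ForecastSet(pd.concat(frames, ignore_index=True))


def structural_violations(df: pd.DataFrame) -> dict[str, list[str]]:
    """Collect structural-invariant violations of a long-format forecast frame.

    Returns a mapping from a distribution-key label (or ``"*"`` for
    table-wide problems) to a list of human-readable violations. An empty
    mapping means the frame is structurally valid.
    """
    problems: dict[str, list[str]] = {}

    def add(key: str, msg: str) -> None:
        problems.setdefault(key, []).append(msg)

    bad_family = set(df["family"]) - FAMILIES
    if bad_family:
        add("*", f"unknown family value(s): {sorted(bad_family)}")
        df = df[df["family"].isin(FAMILIES)]
    if (df["horizon"] < 1).any():
        add("*", "valid date must be after the issue date (horizon >= 1)")

    fam_counts = df.groupby(DISTRIBUTION_KEY, sort=False)["family"].nunique()
    for key in fam_counts[fam_counts > 1].index:
        add("/".join(map(str, key)), "mixed families within one distribution key")

    normal = df[df["family"] == "normal"]
    if len(normal):
        bad = set(normal["parameter"]) - {"mu", "sigma"}
        if bad:
            add("*", f"normal family requires parameters mu/sigma, got: {sorted(bad)}")
        counts = normal.pivot_table(
            index=DISTRIBUTION_KEY, columns="parameter", values="prediction",
            aggfunc="count", fill_value=0,
        )
        for p in ("mu", "sigma"):
            if p not in counts.columns:
                bad_keys = counts.index
            else:
                bad_keys = counts.index[counts[p] != 1]
            for key in bad_keys:
                add("/".join(map(str, key)), f"normal key needs exactly one '{p}' row")
        sigma = normal[normal["parameter"] == "sigma"]
        for _, row in sigma[sigma["prediction"] < 0].iterrows():
            key = "/".join(str(row[c]) for c in DISTRIBUTION_KEY)
            add(key, "sigma must be non-negative")

    ens = df[df["family"] == "ensemble"]
    if len(ens):
        idx = pd.to_numeric(ens["parameter"], errors="coerce")
        if idx.isna().any():
            add("*", "ensemble parameters must be integer member indices")
        else:
            # contiguous 1..m without duplicates <=> min=1, max=size, nunique=size
            g = (
                ens.assign(_idx=idx.astype(int))
                .groupby(DISTRIBUTION_KEY, sort=False)["_idx"]
                .agg(size="size", mn="min", mx="max", nuniq="nunique")
            )
            for key in g.index[g["size"] < 2]:
                add("/".join(map(str, key)), "ensemble key has fewer than 2 members")
            bad = g[(g["size"] >= 2) & ((g["mn"] != 1) | (g["mx"] != g["size"]) | (g["nuniq"] != g["size"]))]
            for key in bad.index:
                add("/".join(map(str, key)),
                    "ensemble member indices must be 1-based contiguous without duplicates")
    return problems


def read_forecast_file(path: str | Path) -> ForecastSet:
    """Read a standardized forecast CSV (or parquet) into a :class:`ForecastSet`.

    Raises :class:`FormatError` naming the column if a required column is
    absent, and :class:`ForecastValidationError` for structural violations
    (negative sigma, mixed families within one key, non-contiguous ensemble
    member indices).
    """
    path = Path(path)
    if path.suffix in {".parquet", ".pq"}:
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype={"parameter": str}, float_precision="round_trip")
    return ForecastSet(df)


def write_forecast_file(fset: ForecastSet, path: str | Path) -> Path:
    """Write a :class:`ForecastSet` to CSV (or parquet by extension).

    Round-trip safe: ``read_forecast_file(write_forecast_file(s)) == s``.
    Dates are ISO-8601; floats use shortest-round-trip repr.
    """
    path = Path(path)
    df = fset.frame[FORECAST_COLUMNS].copy()
    df["reference_datetime"] = df["reference_datetime"].dt.strftime("%Y-%m-%d")
    df["datetime"] = df["datetime"].dt.strftime("%Y-%m-%d")
    if path.suffix in {".parquet", ".pq"}:
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def read_target_file(path: str | Path) -> pd.DataFrame:
    """Read a target CSV into a tidy (site_id, date, variable, observation) frame."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[TARGET_COLUMNS].copy()
    df["date"] = _as_date(df["date"])
    df["observation"] = df["observation"].astype(float)
    dup = df.duplicated(subset=["site_id", "date", "variable"])
    if dup.any():
        raise ForecastValidationError("duplicate (site, date, variable) target rows")
    return df.reset_index(drop=True)


def write_target_file(targets: pd.DataFrame, path: str | Path) -> Path:
    df = targets[TARGET_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
    return Path(path)


@dataclass
class ValidationReport:
    """Completeness report for a forecast set against the submission rules.

    ``violations`` maps a distribution-group label to a list of
    human-readable problems; ``ok`` is true iff no group has any.
    """

    violations: dict[str, list[str]]

    @property
    def ok(self) -> bool:
        return not any(self.violations.values())

    def summary(self) -> str:
        if self.ok:
            return "ok"
        lines = []
        for key, probs in self.violations.items():
            for p in probs:
                lines.append(f"{key}: {p}")
        return "\n".join(lines)


def validate_forecast(
    fset: ForecastSet | pd.DataFrame, required_horizons: range = range(1, 31)
) -> ValidationReport:
    """Check a forecast table for horizon completeness and structural rules.

    Submissions must cover a daily sequence of horizons (by default 1..30
    days ahead) with a daily step. Violations are report content, not
    exceptions. A raw ``DataFrame`` may be passed to audit a submission
    that would be rejected by strict :class:`ForecastSet` construction
    (e.g., a normal key lacking its sigma row).
    """
    required = set(required_horizons)
    if isinstance(fset, ForecastSet):
        df = fset.frame
        violations = {}
    else:
        df = fset.copy()
        missing_cols = [c for c in FORECAST_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"missing required column(s): {', '.join(missing_cols)}")
        df["reference_datetime"] = _as_date(df["reference_datetime"])
        df["datetime"] = _as_date(df["datetime"])
        df["parameter"] = df["parameter"].astype(str)
        df["horizon"] = (df["datetime"] - df["reference_datetime"]).dt.days
        violations = structural_violations(df)
    group_cols = ["model_id", "reference_datetime", "site_id", "variable"]
    for key, grp in df.groupby(group_cols, sort=False):
        label = "/".join(str(k) for k in key)
        probs: list[str] = []
        horizons = set(grp["horizon"].tolist())
        missing = sorted(required - horizons)
        if missing:
            probs.append(f"missing horizons {set(missing)}")
        covered = sorted(h for h in horizons if h in required or min(required) <= h <= max(required))
        gaps = [
            h for h in range(min(covered), max(covered) + 1) if h not in horizons
        ] if covered else []
        gaps = [h for h in gaps if h not in missing]
        if gaps:
            probs.append(f"gaps in daily step at horizons {set(gaps)}")
        if probs:
            violations.setdefault(label, []).extend(probs)
    return ValidationReport(violations=violations)
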