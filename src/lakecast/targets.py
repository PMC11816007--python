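"""Daily surface-mean targets from raw 30-min sensor data.

Raw lake sensor series arrive as 30-min, depth-tagged records with a
boolean QC flag. Targets — the evaluation truth — are produced by
(1) dropping flagged records, records outside a per-variable plausible
range, and records deeper than the surface cutoff (top 1 m of the water
column), then (2) averaging the surviving values per site, calendar day
and variable, provided enough records survive to represent the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["QCConfig", "qc_filter", "daily_aggregate", "SENSOR_COLUMNS"]

SENSOR_COLUMNS = ["site_id", "timestamp", "depth", "variable", "value", "qc_flag"]

#: Plausible-value ranges by variable; records outside are discarded.
DEFAULT_RANGES = {"temperature": (-1.0, 40.0), "oxygen": (0.0, 25.0)}


@dataclass
class QCConfig:
    """Quality-control rules for targets generation.

    Parameters
    ----------
    ranges
        Per-variable allowable value range ``[min, max]``, inclusive.
    surface_cutoff
        Maximum depth (m) considered "surface"; deeper records are
        discarded. Default 1 m.
    min_records
        Minimum surviving 30-min records per day for a valid daily mean;
        days below this produce no target. Default 24 of a nominal 48.
    """

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    surface_cutoff: float = 1.0
    min_records: int = 24

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {var} must satisfy min < max")
        if self.surface_cutoff <= 0:
            raise ValueError("surface cutoff must be positive")


def qc_filter(sensors: pd.DataFrame, config: QCConfig | None = None) -> pd.DataFrame:
    """Remove flagged, out-of-range, and below-cutoff sensor records.

    Order preserving and idempotent. Variables without a configured range
    are range-checked against nothing (kept).
    """
    config = config or QCConfig()
    keep = ~sensors["qc_flag"].astype(bool)
    keep &= sensors["depth"] <= config.surface_cutoff
    for var, (lo, hi) in config.ranges.items():
        is_var = sensors["variable"] == var
        keep &= ~is_var | ((sensors["value"] >= lo) & (sensors["value"] <= hi))
    return sensors[keep].reset_index(drop=True)


def daily_aggregate(sensors: pd.DataFrame, config: QCConfig | None = None) -> pd.DataFrame:
    """Aggregate QC-filtered 30-min records to daily surface means.

    The QC filter is re-applied (idempotent) so callers may pass raw
    series. One target row per (site, date, variable) equal to the
    arithmetic mean over all surviving surface records pooled across
    depths; days with fewer than ``config.min_records`` records emit no
    target. Permutation-invariant in input order.
    """
    config = config or QCConfig()
    clean = qc_filter(sensors, config)
    if not len(clean):
        return pd.DataFrame(columns=["site_id", "date", "variable", "observation"])
    clean = clean.assign(date=pd.to_datetime(clean["timestamp"]).dt.normalize())
    grouped = clean.groupby(["site_id", "date", "variable"], sort=True)["value"].agg(
        ["mean", "count"]
    )
    grouped = grouped[grouped["count"] >= config.min_records]
    out = grouped.reset_index().rename(columns={"mean": "observation"})
    return out[["site_id", "date", "variable", "observation"]]
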