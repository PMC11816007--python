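"""End-to-end synthetic challenge orchestration.

``run_synthetic_challenge`` composes the whole experiment:
simulate lake truths and sensors -> build daily targets -> generate
baseline and model forecast submissions -> score against targets ->
apply the synthesis inclusion rules -> aggregate into a leaderboard and
the standard summary tables (skill by horizon / site, reliability,
bias and spread, climatology divergence). All artifacts are CSV; a
manifest records the seed, a config hash and per-file SHA-256 digests,
so a repeat run with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, io_formats, scoring, targets as targets_mod
from .synthetic_challenge import (
    LakeConfig,
    ModelSpec,
    UncertaintySpec,
    WeatherConfig,
    generate_model_forecasts,
    simulate_air_truth,
    simulate_do_truth,
    simulate_lake_truth,
    simulate_observations,
    simulate_weather_forecasts,
)

__all__ = ["ChallengeConfig", "run_synthetic_challenge", "example_challenge_config"]

logger = logging.getLogger("lakecast")

DOY_BASELINE_ID = "climatology"
PERSISTENCE_ID = "persistence"


@dataclass
class ChallengeConfig:
    """Full declarative specification of one synthetic challenge.

    ``issue_start``/``issue_end``/``issue_step_days`` define the forecast
    issue dates inside the focal year; ``history_years`` is the number of
    calendar years of data simulated before the focal year (the training
    record for climatology and model fitting).
    """

    lakes: list[LakeConfig]
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    models: list[ModelSpec] = field(default_factory=list)
    focal_year: int = 2023
    history_years: int = 4
    issue_start: str = "2023-01-05"
    issue_end: str = "2023-12-01"
    issue_step_days: int = 7
    horizons: tuple[int, int] = (1, 30)
    variables: tuple[str, ...] = ("temperature", "oxygen")
    qc: targets_mod.QCConfig = field(default_factory=targets_mod.QCConfig)

    def __post_init__(self) -> None:
        if not self.lakes:
            raise ValueError("need at least one lake")
        if not self.models:
            raise ValueError("need at least one model")
        if not len(self.issue_dates()):
            raise ValueError("need at least one issue date")

    def issue_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.issue_start, self.issue_end,
                             freq=f"{self.issue_step_days}D")

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChallengeConfig":
        d = dict(d)
        d["lakes"] = [LakeConfig(**_tuplify(lk, ("depths", "ice_window"))) for lk in d["lakes"]]
        if "weather" in d:
            d["weather"] = WeatherConfig(**_tuplify(d["weather"], ("error_growth",)))
        models = []
        for m in d.get("models", []):
            m = _tuplify(m, ("covariates", "variables", "constituents"))
            if "uncertainty" in m and isinstance(m["uncertainty"], dict):
                m["uncertainty"] = UncertaintySpec(**m["uncertainty"])
            models.append(ModelSpec(**m))
        d["models"] = models
        if "qc" in d and isinstance(d["qc"], dict):
            qc = dict(d["qc"])
            if "ranges" in qc:
                qc["ranges"] = {k: tuple(v) for k, v in qc["ranges"].items()}
            d["qc"] = targets_mod.QCConfig(**qc)
        for key in ("horizons", "variables"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChallengeConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)
        return Path(path)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _tuplify(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def _monthly_offsets_int_keys(lake: LakeConfig) -> LakeConfig:
    # YAML round-trips dict keys as strings; normalize back to ints
    if lake.monthly_offsets and any(isinstance(k, str) for k in lake.monthly_offsets):
        lake = dataclasses.replace(
            lake, monthly_offsets={int(k): v for k, v in lake.monthly_offsets.items()}
        )
    return lake


def run_synthetic_challenge(
    config: ChallengeConfig, seed: int, out_dir: str | Path | None = None
) -> dict:
    """Run the full synthetic challenge and return the report bundle.

    Returns a dict with the targets frame, raw and filtered score
    tables, leaderboard, per-horizon/per-site summaries, reliability and
    divergence tables, and the manifest. When ``out_dir`` is given every
    table is also written as CSV (same config + seed => byte-identical
    files).
    """
    config = dataclasses.replace(config, lakes=[_monthly_offsets_int_keys(l) for l in config.lakes])
    issue_dates = config.issue_dates()
    start_year = config.focal_year - config.history_years
    n_years = config.history_years + 1
    h_lo, h_hi = config.horizons
    horizons = range(h_lo, h_hi + 1)

    # -- stage 1: truths, sensors, targets ------------------------------
    all_targets = []
    weather_by_site = {}
    truth_by_site = {}
    for lake in config.lakes:
        temp_truth = simulate_lake_truth(lake, start_year, n_years, config.focal_year, seed)
        truth_by_site[lake.site_id] = temp_truth
        # one extra year so late-season issues keep their full weather horizon
        air_truth = simulate_air_truth(lake, start_year, n_years + 1, config.focal_year, seed)
        weather_by_site[lake.site_id] = simulate_weather_forecasts(
            air_truth, config.weather, issue_dates, seed, site_id=lake.site_id
        )
        sensor_frames = [simulate_observations(temp_truth, lake, seed, "temperature")]
        if "oxygen" in config.variables:
            do_truth = simulate_do_truth(temp_truth, lake, seed)
            sensor_frames.append(simulate_observations(do_truth, lake, seed, "oxygen"))
        sensors = pd.concat(sensor_frames, ignore_index=True)
        lake_targets = targets_mod.daily_aggregate(sensors, config.qc)
        all_targets.append(lake_targets)
        logger.info("site %s: %d sensor records -> %d target days",
                    lake.site_id, len(sensors), len(lake_targets))
    target_table = pd.concat(all_targets, ignore_index=True)

    # -- stage 2: forecasts ---------------------------------------------
    latency = config.lakes[0].latency_days
    specs = list(config.models)
    ids = [s.model_id for s in specs]
    if DOY_BASELINE_ID not in ids:
        specs.append(ModelSpec(model_id=DOY_BASELINE_ID, model_class="baseline",
                               baseline_which="doy", variables=config.variables))
    if PERSISTENCE_ID not in ids:
        specs.append(ModelSpec(model_id=PERSISTENCE_ID, model_class="baseline",
                               baseline_which="persistence", variables=config.variables))

    forecast_sets: dict[str, io_formats.ForecastSet] = {}
    # MMEs last so their constituents exist
    ordered = [s for s in specs if s.model_class != "mme"] + [
        s for s in specs if s.model_class == "mme"
    ]
    for spec in ordered:
        fs = generate_model_forecasts(
            spec, target_table, weather_by_site, issue_dates, seed,
            horizons=horizons, latency_days=latency, constituents=forecast_sets,
        )
        forecast_sets[spec.model_id] = fs
        logger.info("model %s: %d forecast rows", spec.model_id, len(fs))

    # -- stage 3: scoring ------------------------------------------------
    focal_targets = target_table[
        pd.to_datetime(target_table["date"]).dt.year >= config.focal_year
    ]
    score_frames = []
    for model_id, fs in forecast_sets.items():
        if not len(fs):
            continue
        sc = scoring.score_forecasts(fs, focal_targets)
        score_frames.append(sc)
        logger.info("model %s: %d scored forecast-days", model_id, len(sc))
    scores = pd.concat(score_frames, ignore_index=True)

    # -- stage 4: evaluation ---------------------------------------------
    included = evaluation.apply_inclusion_criteria(scores)
    for _, row in included.dropped_models.iterrows():
        logger.warning(
            "dropped %s at %s/%s: scored %.0f%% of evaluated days",
            row["model_id"], row["site_id"], row["variable"], 100 * row["fraction"],
        )
    baseline_scores = included.table[included.table["model_id"] == DOY_BASELINE_ID]
    submitted = included.table
    skill = evaluation.compute_skill(submitted, baseline_scores, DOY_BASELINE_ID)

    leaderboard = (
        evaluation.aggregate_skill(skill.table, by=("model", "variable"))
        .sort_values(["variable", "crps_skill"], kind="stable")
        .reset_index(drop=True)
    )
    skill_by_horizon = evaluation.aggregate_skill(skill.table, by=("model", "horizon", "variable"))
    skill_by_site = evaluation.aggregate_skill(skill.table, by=("model", "site", "variable"))
    reliability = evaluation.interval_coverage(included.table)
    spread_bias = evaluation.bias_and_spread(included.table)
    divergence = evaluation.climatology_divergence(target_table, config.focal_year)

    bundle = {
        "targets": target_table,
        "scores": scores,
        "included_scores": included.table,
        "dropped_models": included.dropped_models,
        "skill": skill.table,
        "leaderboard": leaderboard,
        "skill_by_horizon": skill_by_horizon,
        "skill_by_site": skill_by_site,
        "reliability": reliability,
        "bias_and_spread": spread_bias,
        "divergence": divergence,
        "forecast_sets": forecast_sets,
    }

    if out_dir is not None:
        bundle["manifest"] = _write_bundle(bundle, config, seed, Path(out_dir))
    return bundle


_CSV_TABLES = [
    "leaderboard",
    "skill_by_horizon",
    "skill_by_site",
    "reliability",
    "bias_and_spread",
    "divergence",
    "dropped_models",
    "scores",
]


def _round_trip_format(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def _write_bundle(bundle: dict, config: ChallengeConfig, seed: int, out_dir: Path) -> dict:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {}
    io_formats.write_target_file(bundle["targets"], out_dir / "targets.csv")
    digests["targets.csv"] = _sha256(out_dir / "targets.csv")
    for name in _CSV_TABLES:
        path = out_dir / f"{name}.csv"
        _round_trip_format(bundle[name]).to_csv(path, index=False)
        digests[path.name] = _sha256(path)
    fdir = out_dir / "forecasts"
    fdir.mkdir(exist_ok=True)
    for model_id, fs in bundle["forecast_sets"].items():
        path = fdir / f"{model_id}.csv"
        io_formats.write_forecast_file(fs, path)
        digests[f"forecasts/{model_id}.csv"] = _sha256(path)
    manifest = {
        "seed": seed,
        "config_sha256": config.digest(),
        "version": __version__,
        "files": digests,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# shipped example configuration
# ---------------------------------------------------------------------------


def example_challenge_config() -> ChallengeConfig:
    """The shipped "challenge-shaped" configuration.

    Seven lakes mirroring the structure of a continental lake network:
    two shallow prairie lakes whose focal year runs several degrees
    warmer than climatology in late spring, an ice-free warm-water pair
    with long records, two north-temperate lakes close to climatology,
    and one arctic lake with a short sensor record. Five stylized model
    classes forecast water temperature; two regressions also forecast
    dissolved oxygen. Values describe plausible lakes, not any real
    site.
    """
    warm_spring = {4: 1.5, 5: 3.0, 6: 3.0, 7: 1.5}
    lakes = [
        # anomaly-year prairie pair (ice-covered in winter)
        LakeConfig(site_id="PRA1", mean=12.0, amplitude=13.0, phase_doy=200,
                   ar1_phi=0.85, ar1_sd=0.35, air_coupling=0.15,
                   ice_window=(334, 85), monthly_offsets=warm_spring),
        LakeConfig(site_id="PRA2", mean=12.5, amplitude=12.5, phase_doy=198,
                   ar1_phi=0.85, ar1_sd=0.4, air_coupling=0.15,
                   ice_window=(330, 90),
                   monthly_offsets={4: 1.0, 5: 2.5, 6: 3.0, 7: 1.0}),
        # ice-free warm-water pair, long stable records
        LakeConfig(site_id="WRM1", mean=22.0, amplitude=6.0, phase_doy=205,
                   ar1_phi=0.8, ar1_sd=0.3, air_coupling=0.15, air_ar1_sd=1.5),
        LakeConfig(site_id="WRM2", mean=21.0, amplitude=6.5, phase_doy=207,
                   ar1_phi=0.8, ar1_sd=0.3, air_coupling=0.15, air_ar1_sd=1.5),
        # north-temperate, climatology-consistent
        LakeConfig(site_id="NTM1", mean=11.0, amplitude=11.0, phase_doy=202,
                   ar1_phi=0.82, ar1_sd=0.35, air_coupling=0.15,
                   ice_window=(335, 95)),
        LakeConfig(site_id="NTM2", mean=10.5, amplitude=11.5, phase_doy=201,
                   ar1_phi=0.82, ar1_sd=0.35, air_coupling=0.15,
                   ice_window=(332, 92)),
        # arctic, short deployment
        LakeConfig(site_id="ARC1", mean=6.0, amplitude=8.0, phase_doy=195,
                   ar1_phi=0.8, ar1_sd=0.4, air_coupling=0.15,
                   ice_window=(300, 150), first_year=2022),
    ]
    five = UncertaintySpec(driver=True, parameter=True, process=True,
                           initial_condition=True, observation=True,
                           parameter_sd=0.1, process_sd=0.12,
                           initial_condition_sd=0.2, observation_sd=0.1)
    driver_only = UncertaintySpec(driver=True)
    models = [
        ModelSpec(model_id="heat_exchange", model_class="process", uncertainty=five,
                  covariates=("air_temperature",), k_exchange=0.15),
        ModelSpec(model_id="gbm_like", model_class="ml",
                  uncertainty=UncertaintySpec(driver=True, process=True, process_sd=0.3),
                  covariates=("air_temperature",),
                  variables=("temperature", "oxygen")),
        ModelSpec(model_id="lasso_like", model_class="ml", uncertainty=driver_only,
                  covariates=("air_temperature",)),
        ModelSpec(model_id="harmonic_reg", model_class="empirical",
                  uncertainty=UncertaintySpec(parameter=True, process=True),
                  variables=("temperature", "oxygen")),
        ModelSpec(model_id="pb_baseline_mme", model_class="mme",
                  constituents=("heat_exchange", "climatology")),
    ]
    return ChallengeConfig(lakes=lakes, weather=WeatherConfig(), models=models)
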