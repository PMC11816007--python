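"""Shared fixtures: small synthetic worlds and forecast tables."""

import numpy as np
import pandas as pd
import pytest

from lakecast import (
    ChallengeConfig,
    ForecastSet,
    LakeConfig,
    ModelSpec,
    UncertaintySpec,
    WeatherConfig,
)
from lakecast.io_formats import FORECAST_COLUMNS


def make_normal_frame(model_id="m1", ref="2023-06-01", site="L1",
                      variable="temperature", horizons=range(1, 31),
                      mu=20.0, sigma=1.0):
    """Long-format normal-family forecast frame covering ``horizons``."""
    rows = []
    ref_ts = pd.Timestamp(ref)
    for h in horizons:
        valid = (ref_ts + pd.Timedelta(days=h)).strftime("%Y-%m-%d")
        rows.append((model_id, ref, valid, site, variable, "normal", "mu", mu))
        rows.append((model_id, ref, valid, site, variable, "normal", "sigma", sigma))
    return pd.DataFrame(rows, columns=FORECAST_COLUMNS)


def make_ensemble_frame(model_id="e1", ref="2023-06-01", site="L1",
                        variable="temperature", horizons=(1,), members=(18.0, 19.0, 21.0)):
    rows = []
    ref_ts = pd.Timestamp(ref)
    for h in horizons:
        valid = (ref_ts + pd.Timedelta(days=h)).strftime("%Y-%m-%d")
        for i, value in enumerate(members, start=1):
            rows.append((model_id, ref, valid, site, variable, "ensemble", str(i), value))
    return pd.DataFrame(rows, columns=FORECAST_COLUMNS)


def make_targets(site="L1", variable="temperature", start="2023-06-02", values=(20.0,)):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame(
        {"site_id": site, "date": dates, "variable": variable,
         "observation": np.asarray(values, dtype=float)}
    )


@pytest.fixture
def normal_set():
    return ForecastSet(make_normal_frame())


@pytest.fixture(scope="session")
def quiet_lake():
    """Deterministic lake: pure seasonal cycle, no noise of any kind."""
    return LakeConfig(site_id="QUIET", mean=15.0, amplitude=10.0, phase_doy=200,
                      ar1_phi=0.0, ar1_sd=0.0, obs_noise_sd=0.0,
                      gap_rate=0.0, flag_rate=0.0, outlier_rate=0.0)


def small_challenge_config(**overrides):
    """A 2-lake, 2-model challenge small enough for repeated runs."""
    lakes = [
        LakeConfig(site_id="A", mean=14.0, amplitude=10.0, ar1_phi=0.8, ar1_sd=0.4,
                   air_coupling=0.15, monthly_offsets={5: 3.0, 6: 3.0}),
        LakeConfig(site_id="B", mean=13.0, amplitude=10.0, ar1_phi=0.8, ar1_sd=0.4,
                   air_coupling=0.15),
    ]
    models = [
        ModelSpec(model_id="hx", model_class="process",
                  uncertainty=UncertaintySpec(driver=True, process=True),
                  covariates=("air_temperature",)),
        ModelSpec(model_id="reg", model_class="empirical",
                  uncertainty=UncertaintySpec(parameter=True, process=True)),
    ]
    defaults = dict(
        lakes=lakes, weather=WeatherConfig(), models=models,
        history_years=3, issue_start="2023-02-01", issue_end="2023-10-01",
        issue_step_days=21, variables=("temperature",),
    )
    defaults.update(overrides)
    return ChallengeConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    from lakecast import run_synthetic_challenge

    return run_synthetic_challenge(small_challenge_config(), seed=11)
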