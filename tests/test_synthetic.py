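"""Synthetic challenge generators: truths, sensors, weather, model forecasts."""

import numpy as np
import pandas as pd
import pytest

from lakecast import (
    LakeConfig,
    ModelSpec,
    UncertaintySpec,
    WeatherConfig,
    daily_aggregate,
    generate_model_forecasts,
    simulate_lake_truth,
    simulate_observations,
    simulate_weather_forecasts,
)
from lakecast.baselines import fit_doy_climatology, forecast_doy
from lakecast.synthetic_challenge import pool_mme, simulate_air_truth


class TestLakeTruth:
    def test_noise_free_closed_form_at_peak(self, quiet_lake):
        truth = simulate_lake_truth(quiet_lake, 2022, 1, seed=0)
        at_peak = truth[pd.DatetimeIndex(truth["date"]).dayofyear == 200]
        assert at_peak["value"].iloc[0] == pytest.approx(25.0)
        assert truth["value"].max() == pytest.approx(25.0, abs=1e-6)

    def test_seeded_determinism(self):
        lake = LakeConfig(site_id="L1")
        a = simulate_lake_truth(lake, 2020, 3, focal_year=2022, seed=42)
        b = simulate_lake_truth(lake, 2020, 3, focal_year=2022, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_lake_truth(lake, 2020, 3, focal_year=2022, seed=43)
        assert not a["value"].equals(c["value"])

    def test_ar1_stationary_sd(self):
        """Sample anomaly SD matches 1/sqrt(1 - phi^2) for phi=0.8, sd=1."""
        lake = LakeConfig(site_id="L1", mean=0.0, amplitude=0.0,
                          ar1_phi=0.8, ar1_sd=1.0)
        truth = simulate_lake_truth(lake, 2000, 28, seed=3)  # > 10^4 days
        expected = 1.0 / np.sqrt(1.0 - 0.64)
        assert truth["value"].std() == pytest.approx(expected, rel=0.05)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            LakeConfig(site_id="L1", ar1_phi=1.0)

    def test_monthly_offsets_additive(self, quiet_lake):
        import dataclasses

        shifted = dataclasses.replace(quiet_lake, monthly_offsets={5: 3.0})
        base = simulate_lake_truth(quiet_lake, 2023, 1, focal_year=2023, seed=0)
        offs = simulate_lake_truth(shifted, 2023, 1, focal_year=2023, seed=0)
        delta = offs["value"] - base["value"]
        months = pd.DatetimeIndex(base["date"]).month
        assert np.allclose(delta[months == 5], 3.0)
        assert np.allclose(delta[months != 5], 0.0)


class TestObservations:
    def test_ice_window_empty_including_wrap(self):
        lake = LakeConfig(site_id="L1", ice_window=(330, 90), gap_rate=0.0,
                          flag_rate=0.0)
        truth = simulate_lake_truth(lake, 2022, 1, seed=0)
        obs = simulate_observations(truth, lake, seed=0)
        doys = pd.DatetimeIndex(obs["timestamp"]).dayofyear
        assert not ((doys >= 330) | (doys <= 90)).any()

    def test_noise_free_values_equal_truth(self, quiet_lake):
        truth = simulate_lake_truth(quiet_lake, 2022, 1, seed=0)
        obs = simulate_observations(truth, quiet_lake, seed=0)
        assert len(obs) == 48 * len(truth)
        merged = obs.assign(date=pd.to_datetime(obs["timestamp"]).dt.normalize()).merge(
            truth, left_on="date", right_on="date"
        )
        np.testing.assert_allclose(merged["value_x"], merged["value_y"], atol=1e-12)

    def test_noise_sd_recovered(self):
        lake = LakeConfig(site_id="L1", obs_noise_sd=0.5, gap_rate=0.0, flag_rate=0.0,
                          ar1_sd=0.0)
        truth = simulate_lake_truth(lake, 2022, 1, seed=1)
        obs = simulate_observations(truth, lake, seed=1)  # ~17500 records
        merged = obs.assign(date=pd.to_datetime(obs["timestamp"]).dt.normalize()).merge(
            truth, left_on="date", right_on="date"
        )
        resid = merged["value_x"] - merged["value_y"]
        assert resid.std() == pytest.approx(0.5, rel=0.05)


@pytest.fixture(scope="module")
def air():
    lake = LakeConfig(site_id="L1")
    return simulate_air_truth(lake, 2022, 2, seed=0)


class TestWeather:
    def test_member_and_horizon_counts(self, air):
        wx = simulate_weather_forecasts(air, WeatherConfig(), ["2022-06-01"], seed=0)
        assert wx.ensemble["member"].nunique() == 31
        assert sorted(wx.ensemble["horizon"].unique()) == list(range(1, 36))

    def test_zero_growth_members_equal_truth(self, air):
        cfg = WeatherConfig(error_growth=tuple([0.0] * 35))
        wx = simulate_weather_forecasts(air, cfg, ["2022-06-01"], seed=0)
        truth = air.set_index("date")["value"]
        merged = wx.ensemble.merge(truth.rename("truth"), left_on="datetime", right_index=True)
        np.testing.assert_allclose(merged["value"], merged["truth"], atol=1e-12)

    def test_dispersion_one_is_calibrated(self, air):
        """Ensemble variance approximates the squared error SD per horizon."""
        issues = pd.date_range("2022-02-01", "2022-11-01", freq="2D")
        cfg = WeatherConfig(dispersion=1.0)
        wx = simulate_weather_forecasts(air, cfg, issues, seed=4)
        truth = air.set_index("date")["value"]
        df = wx.ensemble.merge(truth.rename("truth"), left_on="datetime", right_index=True)
        for h in (1, 10, 30):
            sub = df[df["horizon"] == h]
            spread2 = sub.groupby("issue_date")["value"].var(ddof=1).mean()
            err2 = cfg.error_sd(np.array([h]))[0] ** 2
            assert spread2 == pytest.approx(err2, rel=0.10)
            rmse2 = ((sub["value"] - sub["truth"]) ** 2).mean()
            assert rmse2 == pytest.approx(err2, rel=0.10)

    def test_nondecreasing_growth_enforced(self):
        with pytest.raises(ValueError):
            WeatherConfig(error_growth=tuple([1.0] * 34 + [0.5]))

    def test_historic_product_covers_truth_dates(self, air):
        wx = simulate_weather_forecasts(air, WeatherConfig(), ["2022-06-01"], seed=0)
        assert len(wx.historic) == len(air)


@pytest.fixture(scope="module")
def world():
    """One lake with targets, weather, and 100 issue dates at horizon 1."""
    lake = LakeConfig(site_id="L1", ar1_phi=0.8, ar1_sd=0.4, air_coupling=0.15)
    truth = simulate_lake_truth(lake, 2020, 4, focal_year=2023, seed=9)
    air = simulate_air_truth(lake, 2020, 4, focal_year=2023, seed=9)
    obs = simulate_observations(truth, lake, seed=9)
    targets = daily_aggregate(obs)
    issues = pd.date_range("2023-02-01", periods=100, freq="3D")
    wx = simulate_weather_forecasts(air, WeatherConfig(), issues, seed=9, site_id="L1")
    return {"lake": lake, "targets": targets, "weather": {"L1": wx}, "issues": issues}


class TestModelForecasts:
    def test_baseline_equivalence_contract(self, world):
        """A baseline-class spec reproduces the baselines module exactly."""
        spec = ModelSpec(model_id="climatology", model_class="baseline",
                         baseline_which="doy")
        issues = world["issues"][:3]
        fs = generate_model_forecasts(spec, world["targets"], None, issues, seed=9)
        frames = []
        for issue in issues:
            avail = world["targets"][
                pd.to_datetime(world["targets"]["date"]) <= issue - pd.Timedelta(days=2)
            ]
            clim = fit_doy_climatology(avail, as_of=issue)
            frames.append(forecast_doy(clim, issue, range(1, 31),
                                       model_id="climatology", skip_missing=True).frame)
        expected = pd.concat(frames, ignore_index=True)
        pd.testing.assert_frame_equal(
            fs.frame.reset_index(drop=True), expected.reset_index(drop=True)
        )

    def test_driver_only_spec_emits_31_members(self, world):
        spec = ModelSpec(model_id="d", model_class="process",
                         uncertainty=UncertaintySpec(driver=True),
                         covariates=("air_temperature",))
        fs = generate_model_forecasts(spec, world["targets"], world["weather"],
                                      world["issues"][:2], seed=9)
        assert (fs.frame["family"] == "ensemble").all()
        counts = fs.frame.groupby(["reference_datetime", "datetime"])["parameter"].nunique()
        assert (counts == 31).all()

    def test_driver_uncertainty_requires_weather(self, world):
        spec = ModelSpec(model_id="d", model_class="ml",
                         uncertainty=UncertaintySpec(driver=True))
        with pytest.raises(ValueError, match="driver"):
            generate_model_forecasts(spec, world["targets"], None,
                                     world["issues"][:1], seed=9)

    def test_all_sources_spread_exceeds_driver_only(self, world):
        """Adding parameter/process/IC/observation noise widens the ensemble."""
        base = dict(model_class="process", covariates=("air_temperature",))
        d_only = ModelSpec(model_id="a", uncertainty=UncertaintySpec(driver=True), **base)
        all5 = ModelSpec(
            model_id="a",  # same id => same substreams, paired comparison
            uncertainty=UncertaintySpec(driver=True, parameter=True, process=True,
                                        initial_condition=True, observation=True),
            **base,
        )
        h1 = range(1, 2)
        fs_d = generate_model_forecasts(d_only, world["targets"], world["weather"],
                                        world["issues"], seed=9, horizons=h1)
        fs_5 = generate_model_forecasts(all5, world["targets"], world["weather"],
                                        world["issues"], seed=9, horizons=h1)

        def mean_sd(fs):
            return fs.frame.groupby("reference_datetime")["prediction"].std(ddof=1).mean()

        assert mean_sd(fs_5) > mean_sd(fs_d)

    def test_information_leakage_bit_identical(self, world):
        """Perturbing targets after the latency cutoff changes nothing."""
        spec = ModelSpec(model_id="ml", model_class="ml",
                         uncertainty=UncertaintySpec(driver=True, process=True),
                         covariates=("air_temperature",))
        issue = world["issues"][50]
        targets = world["targets"].copy()
        fs_a = generate_model_forecasts(spec, targets, world["weather"], [issue], seed=9)
        perturbed = targets.copy()
        late = pd.to_datetime(perturbed["date"]) > issue - pd.Timedelta(days=2)
        perturbed.loc[late, "observation"] += 100.0
        fs_b = generate_model_forecasts(spec, perturbed, world["weather"], [issue], seed=9)
        pd.testing.assert_frame_equal(fs_a.frame, fs_b.frame)

    def test_generation_is_pure_function_of_seed(self, world):
        spec = ModelSpec(model_id="e", model_class="empirical",
                         uncertainty=UncertaintySpec(parameter=True, process=True))
        a = generate_model_forecasts(spec, world["targets"], None, world["issues"][:3], seed=1)
        b = generate_model_forecasts(spec, world["targets"], None, world["issues"][:3], seed=1)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        c = generate_model_forecasts(spec, world["targets"], None, world["issues"][:3], seed=2)
        assert not a.frame["prediction"].equals(c.frame["prediction"])

    def test_mme_pools_members(self, world):
        spec_a = ModelSpec(model_id="a", model_class="process",
                           uncertainty=UncertaintySpec(driver=True),
                           covariates=("air_temperature",))
        fs_a = generate_model_forecasts(spec_a, world["targets"], world["weather"],
                                        world["issues"][:1], seed=9)
        spec_b = ModelSpec(model_id="climatology", model_class="baseline")
        fs_b = generate_model_forecasts(spec_b, world["targets"], None,
                                        world["issues"][:1], seed=9)
        mme = pool_mme({"a": fs_a, "climatology": fs_b}, "mme", n_quantile_members=31)
        counts = mme.frame.groupby("datetime")["parameter"].nunique()
        assert (counts == 62).all()  # 31 raw + 31 quantile members

    def test_mme_requires_constituents(self):
        with pytest.raises(ValueError, match="2 constituent"):
            ModelSpec(model_id="m", model_class="mme", constituents=("only_one",))
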