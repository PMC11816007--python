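"""Relative skill, inclusion rules, aggregation, reliability, divergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakecast import (
    ForecastSet,
    aggregate_skill,
    apply_inclusion_criteria,
    bias_and_spread,
    climatology_divergence,
    compute_skill,
    interval_coverage,
    score_forecasts,
)

from conftest import make_normal_frame, make_targets


def make_scores(rows):
    """rows: (model_id, site_id, ref, valid, horizon, crps) -> score table."""
    df = pd.DataFrame(
        rows, columns=["model_id", "site_id", "reference_datetime", "datetime",
                       "horizon", "crps"],
    )
    df["variable"] = "temperature"
    df["reference_datetime"] = pd.to_datetime(df["reference_datetime"])
    df["datetime"] = pd.to_datetime(df["datetime"])
    df["forecast_mean"] = 20.0
    df["forecast_sd"] = 1.0
    df["abs_bias"] = df["crps"]
    df["in_80_ci"] = True
    df["in_95_ci"] = True
    df["observation"] = 20.0
    return df


class TestComputeSkill:
    def test_sign_convention(self):
        scores = make_scores([("m", "s", "2023-06-01", "2023-06-02", 1, 0.5)])
        base = make_scores([("climatology", "s", "2023-06-01", "2023-06-02", 1, 0.7)])
        result = compute_skill(scores, base, "climatology")
        assert result.table["crps_skill"].iloc[0] == pytest.approx(-0.2)

    def test_baseline_against_itself_is_zero(self):
        base = make_scores(
            [("climatology", "s", "2023-06-01", f"2023-06-{d:02d}", d - 1, 0.3 * d)
             for d in range(2, 10)]
        )
        result = compute_skill(base, base, "climatology")
        assert (result.table["crps_skill"] == 0).all()

    def test_missing_baseline_day_dropped_and_counted(self):
        scores = make_scores([
            ("m", "s", "2023-06-01", "2023-06-02", 1, 0.5),
            ("m", "s", "2023-06-01", "2023-06-03", 2, 0.5),
        ])
        base = make_scores([("climatology", "s", "2023-06-01", "2023-06-02", 1, 0.7)])
        result = compute_skill(scores, base, "climatology")
        assert len(result.table) == 1
        assert result.n_dropped == 1

    def test_absent_baseline_rejected(self):
        scores = make_scores([("m", "s", "2023-06-01", "2023-06-02", 1, 0.5)])
        with pytest.raises(ValueError, match="absent"):
            compute_skill(scores, scores, "climatology")

    def test_antisymmetry(self):
        a = make_scores([("a", "s", "2023-06-01", "2023-06-02", 1, 0.41)])
        b = make_scores([("b", "s", "2023-06-01", "2023-06-02", 1, 0.73)])
        ab = compute_skill(a, b, "b").table["crps_skill"].iloc[0]
        ba = compute_skill(b, a, "a").table["crps_skill"].iloc[0]
        assert ab == pytest.approx(-ba)


class TestInclusionCriteria:
    @pytest.fixture
    def mixed_table(self):
        """Model 'full' scores all 100 days; 'partial' only 79; horizon 16 present."""
        days = pd.date_range("2023-03-01", periods=100, freq="D")
        rows = []
        for model, n_days in (("full", 100), ("partial", 79)):
            for d in days[:n_days]:
                for h in (1, 16, 20):
                    rows.append((model, "s", (d - pd.Timedelta(days=h)), d, h, 0.5))
        return make_scores(rows)

    def test_horizon_16_rows_removed(self, mixed_table):
        result = apply_inclusion_criteria(mixed_table)
        assert 16 not in set(result.table["horizon"])

    def test_partial_model_dropped_full_retained(self, mixed_table):
        result = apply_inclusion_criteria(mixed_table)
        assert set(result.table["model_id"]) == {"full"}
        assert result.dropped_models["model_id"].tolist() == ["partial"]
        assert result.dropped_models["fraction"].iloc[0] == pytest.approx(0.79)
        n_full = (mixed_table["model_id"] == "full") & (mixed_table["horizon"] != 16)
        assert len(result.table) == int(n_full.sum())

    def test_threshold_boundary_inclusive(self, mixed_table):
        result = apply_inclusion_criteria(mixed_table, min_fraction=0.79)
        assert set(result.table["model_id"]) == {"full", "partial"}


class TestAggregateSkill:
    def test_mean_by_model(self):
        table = make_scores([
            ("m", "s", "2023-06-01", "2023-06-02", 1, 0.5),
            ("m", "s", "2023-06-01", "2023-06-03", 2, 0.5),
        ])
        table["crps_skill"] = [-0.1, -0.3]
        out = aggregate_skill(table, by=("model",))
        assert out["crps_skill"].iloc[0] == pytest.approx(-0.2)
        assert out["n"].iloc[0] == 2

    def test_pooled_mean_differs_from_site_means_when_unbalanced(self):
        table = make_scores(
            [("m", "s1", "2023-06-01", "2023-06-02", 1, 0.5)] * 3
            + [("m", "s2", "2023-06-01", "2023-06-02", 1, 0.5)]
        )
        table["crps_skill"] = [0.0, 0.0, 0.0, 1.0]
        pooled = aggregate_skill(table, by=("model",))["crps_skill"].iloc[0]
        per_site = aggregate_skill(table, by=("model", "site"))["crps_skill"]
        assert pooled == pytest.approx(0.25)
        assert per_site.mean() == pytest.approx(0.5)  # equal-weight site mean differs

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_skill(make_scores([]).iloc[:0], by=("model",))


class TestIntervalCoverage:
    @staticmethod
    def calibrated_scores(n=10_000, sigma=1.0, seed=8):
        """Normal forecasts N(0, sigma) scored on truth drawn from N(0, 1)."""
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(n)
        z80, z95 = stats.norm.ppf(0.9), stats.norm.ppf(0.975)
        df = make_scores(
            [("m", "s", "2023-01-01", "2023-01-02", 1, 0.1)] * n
        )
        df["in_80_ci"] = np.abs(y) <= z80 * sigma
        df["in_95_ci"] = np.abs(y) <= z95 * sigma
        return df

    def test_calibrated_coverage_near_nominal(self):
        table = interval_coverage(self.calibrated_scores())
        p80 = table[table["level"] == 0.80]["proportion_in_ci"].iloc[0]
        p95 = table[table["level"] == 0.95]["proportion_in_ci"].iloc[0]
        assert 0.79 <= p80 <= 0.81
        assert 0.945 <= p95 <= 0.955

    def test_halved_sigma_overconfident(self):
        full = interval_coverage(self.calibrated_scores(sigma=1.0))
        half = interval_coverage(self.calibrated_scores(sigma=0.5))
        for level in (0.80, 0.95):
            a = full[full["level"] == level]["proportion_in_ci"].iloc[0]
            b = half[half["level"] == level]["proportion_in_ci"].iloc[0]
            assert b < a
            assert b < level
        assert (half["classification"] == "overconfident").all()

    def test_coverage_monotone_in_level(self, small_bundle):
        rel = small_bundle["reliability"]
        wide = rel.pivot_table(index=["model_id", "horizon"], columns="level",
                               values="proportion_in_ci")
        assert (wide[0.95] >= wide[0.80]).all()

    def test_normal_80_interval_convention(self):
        """mu +/- 1.28155 sigma; an observation at mu is inside."""
        fs = ForecastSet(make_normal_frame(horizons=[1], mu=20.0, sigma=1.0))
        at_mu = score_forecasts(fs, make_targets(values=(20.0,)))
        edge_in = score_forecasts(fs, make_targets(values=(20.0 + 1.2815,)))
        edge_out = score_forecasts(fs, make_targets(values=(20.0 + 1.2816,)))
        assert bool(at_mu["in_80_ci"].iloc[0])
        assert bool(edge_in["in_80_ci"].iloc[0])
        assert not bool(edge_out["in_80_ci"].iloc[0])


class TestBiasAndSpread:
    def test_single_row_identity(self):
        table = make_scores([("m", "s", "2023-06-01", "2023-06-02", 1, 0.5)])
        table["forecast_sd"] = 1.3
        table["abs_bias"] = 0.7
        out = bias_and_spread(table)
        assert out["mean_sd"].iloc[0] == 1.3
        assert out["mean_abs_bias"].iloc[0] == 0.7

    def test_point_forecasts_zero_spread(self):
        table = make_scores([("m", "s", "2023-06-01", "2023-06-02", h, 0.5)
                             for h in range(1, 6)])
        table["forecast_sd"] = 0.0
        out = bias_and_spread(table)
        assert (out["mean_sd"] == 0.0).all()

    def test_driver_spread_grows_with_horizon(self, small_bundle):
        """Weather-driven ensembles widen along the horizon."""
        out = bias_and_spread(small_bundle["included_scores"])
        hx = out[out["model_id"] == "hx"].sort_values("horizon")
        assert hx["mean_sd"].iloc[-1] > hx["mean_sd"].iloc[0]
        # broadly nondecreasing: regression slope positive
        slope = np.polyfit(hx["horizon"], hx["mean_sd"], 1)[0]
        assert slope > 0


class TestClimatologyDivergence:
    def test_identical_periods_give_zero(self):
        dates = pd.date_range("2022-01-01", "2023-12-31", freq="D")
        values = 15 + 10 * np.cos(2 * np.pi * (dates.dayofyear - 200) / 365.25)
        targets = pd.DataFrame({"site_id": "s", "date": dates,
                                "variable": "temperature", "observation": values})
        out = climatology_divergence(targets, focal_year=2023)
        assert np.allclose(out["delta"], 0.0, atol=0.05)
        assert not out["exceeds_threshold"].any()

    def test_offset_months_recovered(self, quiet_lake):
        import dataclasses

        from lakecast import simulate_lake_truth

        lake = dataclasses.replace(quiet_lake, monthly_offsets={5: 3.0, 6: 3.0})
        truth = simulate_lake_truth(lake, 2021, 3, focal_year=2023, seed=0)
        targets = pd.DataFrame({"site_id": "s", "date": truth["date"],
                                "variable": "temperature",
                                "observation": truth["value"]})
        out = climatology_divergence(targets, focal_year=2023)
        may = out[out["month"] == 5]["delta"].iloc[0]
        jun = out[out["month"] == 6]["delta"].iloc[0]
        aug = out[out["month"] == 8]["delta"].iloc[0]
        assert may == pytest.approx(3.0, abs=0.1)
        assert jun == pytest.approx(3.0, abs=0.1)
        assert abs(aug) < 0.1
        assert out[out["month"] == 5]["exceeds_threshold"].iloc[0]

    def test_month_missing_focal_data_absent(self):
        dates = pd.date_range("2022-01-01", "2023-12-31", freq="D")
        targets = pd.DataFrame({"site_id": "s", "date": dates,
                                "variable": "temperature", "observation": 10.0})
        targets = targets[~((pd.DatetimeIndex(targets["date"]).year == 2023)
                            & (pd.DatetimeIndex(targets["date"]).month == 7))]
        out = climatology_divergence(targets, focal_year=2023)
        assert 7 not in set(out["month"])

    def test_no_history_rejected(self):
        dates = pd.date_range("2023-01-01", "2023-12-31", freq="D")
        targets = pd.DataFrame({"site_id": "s", "date": dates,
                                "variable": "temperature", "observation": 10.0})
        with pytest.raises(ValueError):
            climatology_divergence(targets, focal_year=2023)
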