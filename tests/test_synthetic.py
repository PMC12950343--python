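"""Synthetic study generator: moment targets, count model, ground-truth AF."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heatlag.synthetic import (
    BaselineParams,
    SyntheticUnit,
    TrueSurface,
    WeatherParams,
    default_study_config,
    generate_counts,
    generate_weather,
    hockey_lag0_surface,
    make_study,
    null_surface,
    true_attributable_fraction,
    write_study,
)


class TestWeather:
    def test_marginal_moments_match_municipality_targets(self):
        """Temperature mean/SD within 0.5 degC of the 17.8 (7.7) target over
        a 9-year span."""
        params = WeatherParams.from_targets(temp_mean=17.8, temp_sd=7.7)
        w = generate_weather(3288, params, seed=0)
        t = w["temp_c"]
        assert abs(t.mean() - 17.8) < 0.5
        assert abs(t.std() - 7.7) < 0.5

    def test_degenerate_noise_gives_constant_series(self):
        params = WeatherParams(temp_mean=15.0, temp_seasonal_amplitude=0.0,
                               temp_noise_sd=0.0)
        w = generate_weather(400, params, seed=1)
        np.testing.assert_allclose(w["temp_c"], 15.0)

    def test_fixed_seed_reproduces_series(self):
        params = WeatherParams.from_targets(temp_mean=17.0, temp_sd=8.0)
        w1 = generate_weather(500, params, seed=5)
        w2 = generate_weather(500, params, seed=5)
        pd.testing.assert_frame_equal(w1, w2)

    def test_physical_bounds(self):
        params = WeatherParams.from_targets(temp_mean=17.0, temp_sd=8.0)
        w = generate_weather(2000, params, seed=2)
        assert w["humidity_pct"].between(0, 100).all()
        assert (w["rain_mm"] >= 0).all()
        assert w["sunshine_h"].between(0, 14).all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            generate_weather(100, WeatherParams(17.0, 8.0, 3.0), seed=0)

    def test_invalid_ar1_rejected(self):
        with pytest.raises(ValueError):
            WeatherParams(17.0, 8.0, 3.0, temp_ar1=1.0)


class TestCounts:
    def test_null_surface_recovers_baseline_mean(self):
        params = WeatherParams.from_targets(temp_mean=17.0, temp_sd=8.0)
        w = generate_weather(3000, params, seed=3)
        base = BaselineParams(log_intercept=np.log(2.5))
        counts, *_ , burn = generate_counts(w, base, null_surface(), 21, seed=4)
        m = counts[~burn].mean()
        se = counts[~burn].std() / np.sqrt((~burn).sum())
        assert abs(m - 2.5) < 3 * se

    def test_municipality_scale_target(self):
        """A unit tuned to 17.4 events/day lands within 1.0 of it."""
        cfg = default_study_config(n_units=5)
        unit5 = make_study(cfg, 6)[4]  # the high-volume municipality
        assert cfg["units"][4]["count_mean"] == 17.4
        assert abs(unit5.counts[~unit5.burn_in].mean() - 17.4) < 1.0

    def test_lag0_hockey_slope_recovered_by_regression(self):
        """Truth +0.01 per degC above 20 at lag 0: the empirical log
        rate-ratio between 30 and 20 degC is ~0.1."""
        rng = np.random.default_rng(0)
        params = WeatherParams.from_targets(temp_mean=20.0, temp_sd=8.0)
        w = generate_weather(6000, params, seed=7)
        base = BaselineParams(log_intercept=np.log(20.0))
        surface = hockey_lag0_surface(20.0, 0.01)
        counts, *_ , burn = generate_counts(w, base, surface, 0, seed=8)
        X = sm.add_constant(np.maximum(w["temp_c"].to_numpy() - 20.0, 0.0))
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        assert 10 * res.params[1] == pytest.approx(0.1, abs=0.02)

    def test_overdispersion_calibration(self):
        """Constant-rate null series: variance/mean ratio matches the
        requested inflation factor within 10% at n >= 2000."""
        params = WeatherParams(temp_mean=15.0, temp_seasonal_amplitude=0.0,
                               temp_noise_sd=0.0)
        w = generate_weather(20000, params, seed=9)
        base = BaselineParams(log_intercept=np.log(4.0), overdispersion=1.5)
        counts, *_ , burn = generate_counts(w, base, null_surface(), 21, seed=10)
        ratio = counts[~burn].var() / counts[~burn].mean()
        assert ratio == pytest.approx(1.5, rel=0.10)

    def test_overdispersion_below_one_rejected(self):
        with pytest.raises(ValueError):
            BaselineParams(log_intercept=0.0, overdispersion=0.8)

    def test_dow_effects_must_sum_to_zero(self):
        with pytest.raises(ValueError):
            BaselineParams(log_intercept=0.0, dow_effects=(0.1,) * 7)


class TestTrueAF:
    def _toy_unit(self, contrib):
        n = len(contrib)
        dates = pd.date_range("2020-01-01", periods=n)
        weather = pd.DataFrame(
            {"temp_c": np.linspace(0, 30, n), "humidity_pct": 70.0,
             "rain_mm": 0.0, "sunshine_h": 5.0}, index=dates,
        )
        return SyntheticUnit(
            unit_id="toy", dates=dates, counts=np.ones(n, dtype=int),
            weather=weather, surface=null_surface(),
            baseline=BaselineParams(log_intercept=0.0),
            weather_params=WeatherParams(15.0, 5.0, 2.0), seed=0,
            log_baseline=np.zeros(n), surface_contrib=np.asarray(contrib, float),
            burn_in=np.zeros(n, dtype=bool),
        )

    def test_null_surface_gives_zero(self):
        unit = self._toy_unit(np.zeros(10))
        assert true_attributable_fraction(unit) == 0.0

    def test_ten_day_toy_closed_form(self):
        """5 days at cumulative log-RR 0.1 and 5 at 0, equal baselines:
        AF = 100 (5 e^0.1 + 5 - 10) / (5 e^0.1 + 5)."""
        contrib = np.array([0.1] * 5 + [0.0] * 5)
        unit = self._toy_unit(contrib)
        expected = 100 * (5 * np.e**0.1 + 5 - 10) / (5 * np.e**0.1 + 5)
        assert true_attributable_fraction(unit) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_day_by_day(self):
        rng = np.random.default_rng(4)
        contrib = np.abs(rng.normal(0, 0.1, 15))
        unit = self._toy_unit(contrib)
        lam = np.exp(contrib)
        # cumulative at the true MMT is 0 for this null-kind surface
        brute = 100 * (lam.sum() - len(lam)) / lam.sum()
        assert true_attributable_fraction(unit) == pytest.approx(brute, abs=1e-12)

    def test_monotone_increasing_surface_nonnegative(self):
        cfg = default_study_config(n_units=1)
        cfg["surface"] = hockey_lag0_surface(15.0, 0.02).to_dict()
        unit = make_study(cfg, 11)[0]
        assert true_attributable_fraction(unit) >= 0.0

    def test_truthless_unit_rejected(self):
        unit = self._toy_unit(np.zeros(5))
        unit.log_baseline = None
        with pytest.raises(ValueError):
            true_attributable_fraction(unit)


class TestMakeStudy:
    def test_default_study_shape(self):
        cfg = default_study_config()
        units = make_study(cfg, 1)
        assert len(units) == 17
        spans = [(u.dates[-1] - u.dates[0]).days / 365.25 for u in units]
        assert min(spans) > 4.0 and max(spans) < 10.0

    def test_single_unit_config(self):
        units = make_study(default_study_config(n_units=1), 2)
        assert len(units) == 1

    def test_duplicate_unit_ids_rejected(self):
        cfg = default_study_config(n_units=2)
        cfg["units"][1]["unit_id"] = cfg["units"][0]["unit_id"]
        with pytest.raises(ValueError, match="duplicate"):
            make_study(cfg, 0)

    def test_master_seed_determinism(self):
        cfg = default_study_config(n_units=3)
        u1 = make_study(cfg, 42)
        u2 = make_study(cfg, 42)
        for a, b in zip(u1, u2):
            np.testing.assert_array_equal(a.counts, b.counts)
            pd.testing.assert_frame_equal(a.weather, b.weather)

    def test_subgroup_counts_sum_to_totals(self):
        cfg = default_study_config(n_units=2, subgroup_props={
            "sex": ("men", "women", 0.444), "age": ("lt65", "ge65", 0.218),
        })
        for u in make_study(cfg, 3):
            np.testing.assert_array_equal(u.subgroups["men"] + u.subgroups["women"], u.counts)
            np.testing.assert_array_equal(u.subgroups["lt65"] + u.subgroups["ge65"], u.counts)

    def test_write_study_outputs(self, tmp_path):
        cfg = default_study_config(n_units=2)
        units = make_study(cfg, 5)
        write_study(units, cfg, 5, tmp_path)
        files = sorted(p.name for p in tmp_path.iterdir())
        assert files == ["manifest.yaml", "unit01.csv", "unit02.csv"]
        df = pd.read_csv(tmp_path / "unit01.csv")
        assert list(df.columns) == ["date", "count", "temp_c", "humidity_pct",
                                    "rain_mm", "sunshine_h"]


class TestSurfacePresets:
    def test_null_surface_is_zero_everywhere(self):
        s = null_surface()
        assert not s.cumulative(np.linspace(-10, 40, 9)).any()
        assert not s.contribution(np.array([25.0]), 3).any()

    def test_distributed_surface_cumulative_equals_lag_sum(self):
        s = TrueSurface(kind="hockey_distributed", threshold=18.0, slope=0.03,
                        decay=0.8, max_lag=21)
        x = np.array([25.0])
        total = sum(s.contribution(x, lag)[0] for lag in range(22))
        assert total == pytest.approx(s.cumulative(x)[0], rel=1e-12)

    def test_surface_dict_round_trip(self):
        s = TrueSurface(kind="smooth", center=12.0, curvature=0.2)
        assert TrueSurface.from_dict(s.to_dict()) == s
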