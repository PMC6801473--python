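"""Synthetic-data generator: determinism, calibrated moments, truth surface."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermoyll.simulate import (ConfigError, SimulationConfig, TruthSurface,
                                generate_death_records, generate_pollutants,
                                generate_weather, generate_yll_series,
                                make_cold_heat_truth, make_life_table,
                                simulate_daily_series)


class TestConfig:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ConfigError, match="temp_ar1"):
            SimulationConfig(temp_ar1=1.0)
        with pytest.raises(ConfigError, match="n_days"):
            SimulationConfig(n_days=10)
        with pytest.raises(ConfigError, match="yll_noise_sd"):
            SimulationConfig(yll_noise_sd=-1.0)


class TestWeather:
    def test_degenerate_config_gives_constant_series(self):
        cfg = SimulationConfig(temp_amplitude=0.0, temp_noise_sd=0.0)
        w = generate_weather(cfg)
        np.testing.assert_allclose(w["temperature"], cfg.temp_mean)

    def test_same_seed_bit_identical(self):
        a = simulate_daily_series(SimulationConfig(seed=3))
        b = simulate_daily_series(SimulationConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_daily_series(SimulationConfig(seed=4))
        assert not np.allclose(a["temperature"], c["temperature"])

    def test_default_calibration_moments(self):
        w = generate_weather(SimulationConfig(seed=0))
        t = w["temperature"]
        # stationary SD of the series around its mean
        sd = t.std()
        se = sd / np.sqrt(len(t))
        assert abs(t.mean() - 11.4) < 3 * se * np.sqrt(30)  # autocorrelated
        assert t.min() < 0 < t.max()
        assert 8.0 < sd < 11.0  # near the emulated 9.4 degC
        assert ((w["humidity"] >= 0) & (w["humidity"] <= 100)).all()

    def test_seasonal_peak_in_summer(self):
        w = generate_weather(SimulationConfig(seed=1, temp_noise_sd=0.0))
        peak = w.loc[w["temperature"].idxmax(), "date"]
        assert peak.month == 7


class TestPollutants:
    def test_strictly_positive_any_seed(self):
        for seed in (0, 99, 12345):
            cfg = SimulationConfig(seed=seed)
            p = generate_pollutants(cfg, generate_weather(cfg))
            for c in ("pm10", "no2", "so2", "co", "o3"):
                assert (p[c] > 0).all()

    def test_correlation_sign_matches_coupling(self):
        cfg = SimulationConfig(seed=6, n_days=10_000)
        w = generate_weather(cfg)
        p = generate_pollutants(cfg, w)
        t = p["temperature"]
        for c in ("pm10", "no2", "so2", "co"):
            assert np.corrcoef(t, np.log(p[c]))[0, 1] < -0.2
        assert np.corrcoef(t, np.log(p["o3"]))[0, 1] > 0.2

    def test_zero_coupling_uncorrelated(self):
        cfg = SimulationConfig(seed=7, n_days=10_000)
        w = generate_weather(cfg)
        p = generate_pollutants(cfg, w, couplings={k: 0.0 for k in
                                                   ("pm10", "no2", "so2",
                                                    "co", "o3")})
        r = np.corrcoef(p["temperature"], np.log(p["pm10"]))[0, 1]
        assert abs(r) < 3 / np.sqrt(10_000) * 1.5


class TestYLLSeries:
    def test_null_truth_iid_gaussian(self):
        cfg = SimulationConfig(seed=8)
        y = simulate_daily_series(cfg, with_pollutants=False)["all"]
        assert y.mean() == pytest.approx(420.5, abs=3 * 60 / np.sqrt(1461))
        assert abs(stats.skew(y)) < 0.25
        assert abs(stats.kurtosis(y)) < 0.5

    def test_zero_noise_null_truth_constant(self):
        cfg = SimulationConfig(seed=9, yll_noise_sd=0.0)
        y = simulate_daily_series(cfg, with_pollutants=False)["all"]
        np.testing.assert_allclose(y, 420.5)

    def test_cold_effect_appears_in_configured_lag_window(self):
        # truth acts at lags 10-20 only: cross-correlation of cold exposure
        # with YLL should peak inside that window, not at lag 0
        truth = make_cold_heat_truth(cold_lags=(10, 20), heat_cumulative=0.0,
                                     cold_cumulative=400.0)
        cfg = SimulationConfig(seed=10, truth_surface=truth, yll_noise_sd=10.0)
        d = simulate_daily_series(cfg, with_pollutants=False)
        cold = np.maximum(0, 2.45 - d["temperature"].to_numpy())
        y = d["all"].to_numpy()
        def xcorr(lag):
            return np.corrcoef(cold[: len(y) - lag], y[lag:])[0, 1]
        inside = max(xcorr(l) for l in range(10, 21))
        assert inside > xcorr(0) + 0.05
        assert inside > xcorr(28) + 0.05

    def test_unknown_pollutant_effect_name_rejected(self):
        cfg = SimulationConfig(seed=1, pollutant_effects={"xx": 1.0})
        w = generate_weather(cfg)
        with pytest.raises(ConfigError, match="xx"):
            generate_yll_series(cfg, w)


class TestTruthSurface:
    def test_zero_at_reference_for_all_lags(self, truth):
        for lag in (0, 3, 12, 30):
            assert truth.value(np.array([truth.ref_temp]), lag)[0] \
                == pytest.approx(0.0, abs=1e-10)

    def test_needs_exactly_one_representation(self):
        from thermoyll.crossbasis import temperature_crossbasis_spec
        spec = temperature_crossbasis_spec(boundary_knots=(-20, 36))
        with pytest.raises(ConfigError):
            TruthSurface(spec, ref_temp=0.0)

    def test_projection_close_to_closed_form(self):
        closed = make_cold_heat_truth(project=False)
        proj = make_cold_heat_truth(project=True)
        # the smooth 16-lag cold profile lies almost inside the lag-spline
        # space; its cumulative contrast survives projection nearly intact
        a = closed.cumulative_contrast(-8.0, 2.45)
        b = proj.cumulative_contrast(-8.0, 2.45)
        assert b == pytest.approx(a, rel=0.05)
        # the sharp 3-day heat spike is smeared by the log-lag basis: still
        # positive, still concentrated in the first week
        heat_total = proj.cumulative_contrast(28.0, 19.7)
        heat_early = proj.cumulative_contrast(28.0, 19.7, (0, 6))
        assert heat_total > 0
        assert heat_early > 0.9 * heat_total

    def test_recorded_truth_matches_effect_target(self, truth, noiseless_fit,
                                                  noiseless_daily):
        # the invariant tying generator to estimator: surface contrast at the
        # cold percentiles equals what the fitted model recovers (no noise)
        from thermoyll.effects import temperature_percentiles
        t = noiseless_daily["temperature"].to_numpy()
        p1, p25 = temperature_percentiles(t, [0.01, 0.25])
        est = noiseless_fit.cumulative_effect(p1, p25, (0, 30))
        assert est.estimate == pytest.approx(
            truth.cumulative_contrast(p1, p25), abs=1e-8)

    def test_incompatible_max_lag_rejected(self):
        truth = make_cold_heat_truth(max_lag=30)
        with pytest.raises(ConfigError):
            truth.daily_contribution(np.zeros(20))

    def test_json_sidecar_fields(self, truth, tmp_path):
        import json
        p = tmp_path / "truth.json"
        truth.to_json(p)
        payload = json.loads(p.read_text())
        assert payload["representation"] == "coefficients"
        assert len(payload["theta"]) == 25


class TestDeathRecords:
    def test_zero_rate_gives_empty_list(self):
        lt = make_life_table()
        recs, _ = generate_death_records(
            SimulationConfig(seed=1, deaths_per_day_mean=0.0), lt)
        assert recs == []

    def test_poisson_daily_count_moment(self):
        lt = make_life_table()
        cfg = SimulationConfig(seed=2, n_days=1461, deaths_per_day_mean=29.4)
        recs, _ = generate_death_records(cfg, lt)
        mean = len(recs) / cfg.n_days
        se = np.sqrt(29.4 / cfg.n_days)
        assert abs(mean - 29.4) < 3 * se

    def test_all_cv_causes_collapse_strata(self):
        from thermoyll.yll import aggregate_daily
        lt = make_life_table()
        cfg = SimulationConfig(seed=3, n_days=90, deaths_per_day_mean=5.0)
        recs, _ = generate_death_records(cfg, lt, causes=(("I64", 1.0),))
        cal = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
        out = aggregate_daily(recs, lt, cal)
        np.testing.assert_allclose(out["cv_ge65"], out["nonacc_ge65"],
                                   rtol=1e-12)
        np.testing.assert_allclose(out["nonacc_lt65"] + out["nonacc_ge65"],
                                   out["all"], rtol=1e-12)

    def test_life_table_monotone_and_positive(self):
        lt = make_life_table()
        for sex in ("male", "female"):
            ex = [lt.expected_remaining(2015, sex, a) for a in range(101)]
            assert all(np.diff(ex) < 0)
            assert min(ex) > 0
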