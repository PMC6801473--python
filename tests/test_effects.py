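"""Percentile contrasts, delta-method CIs and table-style summarization."""

from types import SimpleNamespace

import numpy as np
import pytest

from thermoyll.effects import (ContrastDefinition, EffectEstimate,
                               cumulative_effect, lag_curve, lag_effect,
                               run_sensitivity, summarize_curve,
                               temperature_percentiles)
from thermoyll.model import ModelConfig, TemperatureYLLModel
from thermoyll.simulate import SimulationConfig, simulate_daily_series


class TestPercentiles:
    def test_linear_interpolation_rule(self):
        assert temperature_percentiles(np.arange(1, 101), [0.25])[0] \
            == pytest.approx(25.75)

    def test_constant_series(self):
        vals = temperature_percentiles(np.full(50, 3.2), [0.01, 0.5, 0.99])
        assert (vals == 3.2).all()

    def test_probs_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            temperature_percentiles(np.arange(10), [0.0])
        with pytest.raises(ValueError):
            temperature_percentiles(np.arange(10), [1.5])

    def test_contrast_ordering_enforced(self):
        with pytest.raises(ValueError, match="degenerate"):
            ContrastDefinition().resolve(np.full(100, 1.0))


class TestEffects:
    def test_null_contrast_zero_with_zero_width(self, noisy_fit):
        e = lag_effect(noisy_fit, 5.0, 5.0, 3)
        assert e.estimate == 0.0 and e.ci_low == 0.0 and e.ci_high == 0.0
        assert not e.significant

    def test_antisymmetry_at_every_lag(self, noisy_fit):
        for lag in range(0, 31, 5):
            a = lag_effect(noisy_fit, -5.0, 2.0, lag)
            b = lag_effect(noisy_fit, 2.0, -5.0, lag)
            assert a.estimate == pytest.approx(-b.estimate, abs=1e-10)
            assert a.sd == pytest.approx(b.sd, abs=1e-10)

    def test_cumulative_equals_sum_of_single_lags(self, noisy_fit):
        curve = lag_curve(noisy_fit, -5.0, 2.0)
        cum = cumulative_effect(noisy_fit, -5.0, 2.0, (0, 30))
        assert cum.estimate == pytest.approx(
            sum(e.estimate for e in curve), abs=1e-10)

    def test_window_zero_equals_lag_zero(self, noisy_fit):
        a = cumulative_effect(noisy_fit, -5.0, 2.0, (0, 0))
        b = lag_effect(noisy_fit, -5.0, 2.0, 0)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.sd == pytest.approx(b.sd, abs=1e-12)

    def test_lag_out_of_range_rejected(self, noisy_fit):
        with pytest.raises(ValueError, match="lag"):
            lag_effect(noisy_fit, -5.0, 2.0, 31)
        with pytest.raises(ValueError, match="max_lag"):
            cumulative_effect(noisy_fit, -5.0, 2.0, (0, 45))

    def test_delta_ci_matches_mvn_sampling(self, noisy_fit):
        from thermoyll.effects import contrast_vector

        rng = np.random.default_rng(8)
        sl = noisy_fit.layout["temperature"]
        beta = noisy_fit.params[sl]
        cov = noisy_fit.cov_params[sl, sl]
        v = contrast_vector(noisy_fit.temp_crossbasis, -5.0, 2.0, range(31))
        draws = rng.multivariate_normal(beta, cov, size=10_000) @ v
        eff = cumulative_effect(noisy_fit, -5.0, 2.0, (0, 30))
        mc_se = eff.sd / np.sqrt(2 * 10_000)  # SE of a sampled SD
        assert draws.std(ddof=1) == pytest.approx(eff.sd, abs=5 * mc_se + 0.03 * eff.sd)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        width = eff.ci_high - eff.ci_low
        assert lo == pytest.approx(eff.ci_low, abs=0.05 * width)
        assert hi == pytest.approx(eff.ci_high, abs=0.05 * width)

    def test_invariant_to_temperature_block_reparameterization(self, noisy_fit):
        # refit with the temperature columns recombined by an invertible map;
        # the contrast functional must be unchanged
        from thermoyll.model import fit_gaussian

        model = noisy_fit.model
        d = model.design
        X = d.matrix[d.valid_rows].copy()
        sl = d.layout["temperature"]
        rng = np.random.default_rng(4)
        k = sl.stop - sl.start
        A = rng.normal(size=(k, k)) + 5 * np.eye(k)
        X[:, sl] = X[:, sl] @ A
        fr = fit_gaussian(X, model.endog[d.valid_rows], layout=d.layout)

        class Reparam:
            params = fr.params
            cov_params = fr.cov_params
            layout = fr.layout
            temp_crossbasis = noisy_fit.temp_crossbasis

        # with columns recombined as X·A the coefficients become A^{-1}β, so
        # the same functional is vᵀβ = (Aᵀv)ᵀ(A^{-1}β)
        orig = cumulative_effect(noisy_fit, -5.0, 2.0, (0, 30))
        from thermoyll.effects import contrast_vector
        v = contrast_vector(noisy_fit.temp_crossbasis, -5.0, 2.0, range(31))
        vA = A.T @ v
        est = vA @ fr.params[sl]
        sd = np.sqrt(vA @ fr.cov_params[sl, sl] @ vA)
        assert est == pytest.approx(orig.estimate, abs=1e-6)
        assert sd == pytest.approx(orig.sd, abs=1e-6)


def _fake_curve(flags, estimates=None, cumulative=False):
    out = []
    for i, f in enumerate(flags):
        est = estimates[i] if estimates is not None else (5.0 if f else 0.1)
        half = est - 0.01 if f else est + 1.0
        out.append(EffectEstimate(
            target=-5, ref=2, lag=(0, i) if cumulative else i,
            estimate=est, ci_low=est - half, ci_high=est + half))
    return out


class TestSummarize:
    def test_single_run(self):
        flags = [i in range(5, 13) for i in range(31)]
        est = [float(i == 7) * 9.5 + (0.5 if f else 0.0)
               for i, f in enumerate(flags)]
        s = summarize_curve(_fake_curve(flags, est))
        assert s.significant_duration == "Lag 5–12"
        assert s.strongest_lag == "Lag 7"

    def test_two_runs_match_reported_format(self):
        flags = [(5 <= i <= 14) or (23 <= i <= 29) for i in range(31)]
        s = summarize_curve(_fake_curve(flags))
        assert s.significant_duration == "Lag 5–14, lag 23–29"

    def test_nothing_significant_renders_dashes(self):
        s = summarize_curve(_fake_curve([False] * 31))
        assert (s.significant_duration, s.strongest_lag, s.highest_yll) \
            == ("-", "-", "-")

    def test_single_lag_run(self):
        flags = [i == 1 for i in range(31)]
        s = summarize_curve(_fake_curve(flags))
        assert s.significant_duration == "Lag 1"
        assert s.strongest_lag == "Lag 1"

    def test_cumulative_window_notation(self):
        flags = [9 <= i <= 30 for i in range(31)]
        s = summarize_curve(_fake_curve(flags, cumulative=True), cumulative=True)
        assert s.significant_duration == "Lag 0–9 to 30"
        assert s.strongest_lag.startswith("Lag 0–")

    def test_cumulative_single_window(self):
        flags = [i == 30 for i in range(31)]
        s = summarize_curve(_fake_curve(flags, cumulative=True), cumulative=True)
        assert s.significant_duration == "Lag 0–30"

    def test_strongest_tie_broken_by_smaller_lag(self):
        flags = [i in (4, 9) for i in range(12)]
        est = [7.0 if f else 0.0 for f in flags]
        s = summarize_curve(_fake_curve(flags, est))
        assert s.strongest_lag == "Lag 4"

    def test_highest_yll_formatting(self):
        flags = [i == 3 for i in range(5)]
        est = [13.24 if f else 0.0 for f in flags]
        curve = [EffectEstimate(target=-5, ref=2, lag=i, estimate=e,
                                ci_low=e - 11.71, ci_high=e + 11.72)
                 for i, e in enumerate(est)]
        s = summarize_curve(curve)
        assert s.highest_yll == "13.24 (1.53, 24.96)"


@pytest.fixture(scope="module")
def small_daily(truth):
    cfg = SimulationConfig(seed=77, truth_surface=truth, yll_noise_sd=60.0)
    return simulate_daily_series(cfg, with_pollutants=True)


class TestSensitivity:
    def test_grid_of_one_equals_base_analysis(self, small_daily):
        base = ModelConfig(pollutants=("pm10",))
        table = run_sensitivity(small_daily, base,
                                grid={"max_lag": [30]})
        assert len(table) == 1 and table.iloc[0]["error"] == ""
        res = TemperatureYLLModel(small_daily, base).fit()
        eff = res.cold_effect()
        assert table.iloc[0]["cold_estimate"] == pytest.approx(eff.estimate)

    def test_estimates_stable_across_lag_window(self, small_daily):
        # truth acts only at lags <= 20: max_lag 25 vs 30 agree within CIs
        base = ModelConfig(pollutants=())
        table = run_sensitivity(small_daily, base,
                                grid={"max_lag": [25, 30]})
        a, b = table.iloc[0], table.iloc[1]
        assert a["cold_ci_low"] < b["cold_estimate"] < a["cold_ci_high"]

    def test_pollutant_removal_innocuous_when_no_pollutant_effect(
            self, small_daily):
        base = ModelConfig(pollutants=("pm10", "no2", "so2", "co", "o3"))
        table = run_sensitivity(
            small_daily, base,
            grid={"pollutants": [base.pollutants, ()]})
        a, b = table.iloc[0], table.iloc[1]
        assert abs(a["cold_estimate"] - b["cold_estimate"]) \
            < (a["cold_ci_high"] - a["cold_ci_low"]) / 2

    def test_failures_recorded_per_row(self, small_daily):
        base = ModelConfig(pollutants=())
        table = run_sensitivity(small_daily, base,
                                grid={"max_lag": [30, 100_000]})
        assert table.iloc[0]["error"] == ""
        assert table.iloc[1]["error"] != ""
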