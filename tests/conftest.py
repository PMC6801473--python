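import numpy as np
import pytest

from thermoyll.model import ModelConfig, TemperatureYLLModel
from thermoyll.simulate import (SimulationConfig, TRUTH_BOUNDARY_KNOTS,
                                make_cold_heat_truth, simulate_daily_series)


@pytest.fixture(scope="session")
def truth():
    """Delayed cold effect (lags 5-20) + immediate heat effect (lags 0-2),
    representable on the model's own cross-basis family."""
    return make_cold_heat_truth()


@pytest.fixture(scope="session")
def noiseless_daily(truth):
    cfg = SimulationConfig(seed=101, truth_surface=truth, yll_noise_sd=0.0)
    return simulate_daily_series(cfg, with_pollutants=False)


@pytest.fixture(scope="session")
def matched_config():
    """Model config sharing the truth surface's fixed basis support."""
    return ModelConfig(pollutants=(), temp_boundary_knots=TRUTH_BOUNDARY_KNOTS)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_daily, matched_config):
    return TemperatureYLLModel(noiseless_daily, matched_config).fit()


@pytest.fixture(scope="session")
def noisy_fit(truth, matched_config):
    cfg = SimulationConfig(seed=202, truth_surface=truth, yll_noise_sd=60.0)
    daily = simulate_daily_series(cfg, with_pollutants=False)
    return TemperatureYLLModel(daily, matched_config).fit()
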