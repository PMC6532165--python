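import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdlr import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ph_config():
    """Proportional-hazards generative design: beta = log 2, exponential times."""
    return SimulationConfig(n=500, beta=np.log(2.0), seed=20240)


@pytest.fixture(scope="session")
def ph_data(ph_config):
    return simulate_dataset(ph_config)


@pytest.fixture(scope="session")
def ph_data_large():
    return simulate_dataset(SimulationConfig(n=2000, beta=np.log(2.0), seed=777))


@pytest.fixture(scope="session")
def null_data_large():
    """Marker independent of survival."""
    return simulate_dataset(SimulationConfig(n=2000, beta=0.0, seed=555))


@pytest.fixture(scope="session")
def uncensored_data():
    """No censoring mechanism: every subject fails."""
    return simulate_dataset(SimulationConfig(
        n=400, beta=np.log(2.0), censor_scale=1e12, max_followup=1e12, seed=99))


@pytest.fixture(scope="session")
def tiny_data():
    """Hand-sized dataset with a mix of events and censorings."""
    from tdlr import SurvivalDataset
    return SurvivalDataset(
        time=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        event=[1, 0, 1, 1, 0, 1, 1, 0],
        marker=[0.5, -1.2, 1.8, 0.1, -0.4, 2.2, -0.9, 0.3])
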