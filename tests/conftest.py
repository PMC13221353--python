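import numpy as np
import pytest

from mnarps.simgen import SimulationConfig, calibrate_coefficients, simulate_dataset


@pytest.fixture(scope="session")
def small_masked_dataset():
    """n=200, p=6, MAR at 30%: the workhorse fixture for imputer tests."""
    cfg = SimulationConfig(n=200, p=6, missing_rate=0.3, mechanism="MAR", seed=11)
    ds, params = simulate_dataset(cfg)
    return cfg, params, ds


@pytest.fixture(scope="session")
def calibrated_params_p10():
    cfg = SimulationConfig(n=2000, p=10, seed=42)
    return cfg, calibrate_coefficients(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
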