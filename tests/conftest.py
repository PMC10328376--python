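import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phuzsim as pz
from phuzsim.params import CellConfig, KineticParams, SimulationConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibrated_kinetics() -> KineticParams:
    return pz.default_kinetics()


@pytest.fixture(scope="session")
def calibrated_cell() -> CellConfig:
    return pz.default_cell()


@pytest.fixture
def fast_config(calibrated_kinetics, calibrated_cell) -> SimulationConfig:
    """Short, small ensemble for cheap behavioural tests."""
    return SimulationConfig(
        kinetics=calibrated_kinetics,
        cell=calibrated_cell,
        dt=0.05,
        duration=60.0,
        n_runs=20,
        seed=42,
    )


@pytest.fixture
def static_config() -> SimulationConfig:
    """All rates zero, no diffusion: nothing should move."""
    return SimulationConfig(
        kinetics=KineticParams.zero(),
        cell=CellConfig(length=3.5, nucleus_diffusion_coeff=0.0),
        dt=0.01,
        duration=1.0,
        n_runs=1,
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
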