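import pytest

from cpbsim.control import ControllerConfig
from cpbsim.plant import GLYCERIN_LIKE, PlantParams, SensorConfig


@pytest.fixture
def example_params() -> PlantParams:
    """The worked-example parameter set used by the static-map oracles."""
    return PlantParams(
        resistance_R=1.0,
        occluder_resistance_dR0=0.1,
        full_open_flow_Q0=5.0,
        shape_A=0.01,
        shape_K=0.08,
        dead_time_L=0.5,
        time_constant_T=2.0,
    )


@pytest.fixture
def glycerin() -> PlantParams:
    return GLYCERIN_LIKE


@pytest.fixture
def noiseless_sensor() -> SensorConfig:
    return SensorConfig(flow_noise_sd=0.0, level_noise_sd=0.0, level_quantum=0.0)


@pytest.fixture
def controller() -> ControllerConfig:
    return ControllerConfig()
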