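import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmnsim.config import ModelConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def warp_scale(config) -> float:
    """Native-time units to ms, as the ERP forward model defines it."""
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * config.envelope.width
    return config.observation.stimulus_duration_ms / fwhm
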