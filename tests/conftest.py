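import numpy as np
import pytest

from bbbflow.config import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    """Default acquisition/simulation settings."""
    return CohortConfig()


@pytest.fixture
def quiet_config():
    """Noise-free settings for exactness checks."""
    return CohortConfig(snr=0.0, noise_model="none", region_noise_sd=0.0,
                        patient_slope_sd_1e3=0.0)
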