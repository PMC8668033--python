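import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biokin.synthetic import SyntheticSpineConfig, generate_exam, generate_reference_surrogate

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def zero_noise_config():
    return SyntheticSpineConfig(noise_sd_fraction=0.0, seed=7)


@pytest.fixture(scope="session")
def reference():
    return generate_reference_surrogate()


@pytest.fixture(scope="session")
def clean_exam(zero_noise_config):
    """A noise-free 3-pose cervical exam (landmark table + calibration)."""
    return generate_exam(zero_noise_config, "S01", "A")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
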