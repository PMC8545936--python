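import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitfall.synthetic import WalkSpec, generate_walk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free 16-m walk with its ground truth (deterministic)."""
    spec = WalkSpec(walk_distance=16.0, noise_sd=0.0, gyro_noise_sd=0.0)
    return generate_walk(spec, seed=42)


@pytest.fixture(scope="session")
def noisy_walk():
    """Walk with the default noise level."""
    return generate_walk(WalkSpec(walk_distance=16.0), seed=7)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
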