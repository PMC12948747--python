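import numpy as np
import pytest

from facekin import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale null study: 5/group, 3 repetitions, short trials."""
    return SimulationConfig(
        n_per_group=5, n_repetitions=3, frames_cued=54,
        frames_spoken_mean=40, frames_spoken_jitter=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def zero_noise_config():
    """Deterministic study: no subject/repetition/residual variation."""
    return SimulationConfig(
        n_per_group=2, n_repetitions=3, frames_cued=54,
        frames_spoken_mean=40, frames_spoken_jitter=0,
        subject_sd=0.0, repetition_sd=0.0, residual_sd=0.0,
        landmark_noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def zero_noise_dataset(zero_noise_config):
    return generate_dataset(zero_noise_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
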