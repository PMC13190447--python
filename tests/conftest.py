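import numpy as np
import pytest

from headkin.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_participants=2, trials_per_type=2, seed=7)


@pytest.fixture(scope="session")
def small_records(small_config):
    """2 participants x 4 trials x 2 cameras = 16 trial records."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_records():
    """The full default study design: 10 participants x 10 trials x 2 cameras."""
    return generate_dataset(SimConfig(seed=0))
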