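import numpy as np
import pytest

from subdecode.synthetic import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale synthetic study: 16 words, 6 sensors at 100 Hz."""
    return SyntheticConfig(
        n_stems=8, n_suffixes=2, dim=10, n_sensors=6, sfreq=100.0, snr=5.0, seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return make_dataset(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
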