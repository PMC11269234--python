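import numpy as np
import pytest

from ictalemo.feature_extraction import build_feature_matrix
from ictalemo.synthetic_eeg import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_per_class=12, fs=200.0, duration=5.12, ictal_amplitude_ratio=4.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_fm(small_dataset):
    """24 x 512 feature matrix from the small synthetic collection."""
    return build_feature_matrix(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
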