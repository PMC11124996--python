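import numpy as np
import pytest

from specfrac import SyntheticConfig, generate_dataset, sg_smooth


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic campaign at the study conditions (60 x 1481)."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """Reduced grid for fast pipeline-level tests."""
    return SyntheticConfig(n_samples=24, seed=5, wl_start=350, wl_end=900)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_smoothed(small_dataset):
    return sg_smooth(small_dataset.spectra)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
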