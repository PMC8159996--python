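import numpy as np
import pytest

from yieldnet import synth


@pytest.fixture(scope="session")
def tiny_config() -> synth.GeneratorConfig:
    """Small but full-shape generator configuration for unit tests."""
    return synth.GeneratorConfig(
        n_locations=5, n_years=4, grid=(12, 12), n_bins=8, seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """Histogram dataset (20 location-years) plus its binning scheme and truth."""
    return synth.generate_histogram_dataset(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
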