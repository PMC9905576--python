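import numpy as np
import pytest

import pinncal as pc


@pytest.fixture(scope="session")
def default_grid():
    return pc.make_wavelength_grid(350, 1049, 700)


@pytest.fixture(scope="session")
def n01_small():
    """A small N01 draw shared by read-only tests."""
    return pc.synthesize_dataset(pc.ScenarioConfig("N01", n_samples=20, seed=11))


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest grid compatible with the pooling chain, in float64."""
    return pc.ModelConfig(input_length=140, dtype="float64")
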