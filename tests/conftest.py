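import numpy as np
import pytest

from hemolyzer.phantoms import sample_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30 phantoms (10 per class) at full tube resolution."""
    return sample_dataset(10, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
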