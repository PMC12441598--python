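import numpy as np
import pytest

SEED = 20_250_923  # fixed once for the whole suite


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test."""
    return np.random.default_rng(SEED)
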