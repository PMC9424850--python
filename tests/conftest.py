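import numpy as np
import pytest

from tapfatigue import synthetic as syn


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete two-height session (12 cycles)."""
    return syn.generate_session(syn.default_config(seed=1, n_cycles=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
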