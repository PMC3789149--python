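import numpy as np
import pytest

from phytolattice import SimConfig, default_community


@pytest.fixture(scope="session")
def community10():
    """Default ten-species community (local-interaction mortality 0.3)."""
    return default_community(10)


@pytest.fixture(scope="session")
def community10_global():
    """Default ten-species community with global-interaction mortality 0.5."""
    return default_community(10, mortality=0.5)


@pytest.fixture
def tiny_cfg():
    """A fast, fully deterministic configuration for unit tests."""
    return SimConfig(P=14.5, mode="local", L=40, steps=50, seed=123,
                     record_every=10)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
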