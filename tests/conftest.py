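import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from synaptica.patterns import PatternSet


@pytest.fixture
def tiny_patterns():
    """Hand-checkable 4x4 memory: u^1 actives {0,1}, v^1 actives {0,2}."""
    return PatternSet(m=4, n=4,
                      u=[np.array([0, 1])], v=[np.array([0, 2])],
                      k=2, l=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
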