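import numpy as np
import pytest

from ipdpop import DEFAULT_MATRIX


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def matrix():
    return DEFAULT_MATRIX
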