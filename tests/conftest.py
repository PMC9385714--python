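import numpy as np
import pytest

from ribonet.synthetic_data import DEFAULT_WT, default_locus_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wt():
    return DEFAULT_WT


@pytest.fixture
def locus_map8():
    return default_locus_map(8)
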