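import numpy as np
import pytest

from stdtlab.layout import biosemi64_layout
from stdtlab.preprocess import VolumeGrid


@pytest.fixture(scope="session")
def layout():
    return biosemi64_layout()


@pytest.fixture(scope="session")
def grid(layout):
    return VolumeGrid(layout)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
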