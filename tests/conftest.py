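import numpy as np
import pytest

from cowpose.geometry import CameraModel
from cowpose.schemes import ear_scheme, head_scheme


@pytest.fixture(scope="session")
def head():
    return head_scheme()


@pytest.fixture(scope="session")
def ear():
    return ear_scheme()


@pytest.fixture
def cam():
    return CameraModel.default((640, 480))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
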