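import numpy as np
import pytest

from coopssl.geometry import MicArrayGeometry
from coopssl.simulate import HenCallModel


@pytest.fixture(scope="session")
def geometry() -> MicArrayGeometry:
    """Default Kinect-style array: gaps 149/40/37 mm, triple (0, 1, 3)."""
    return MicArrayGeometry()


@pytest.fixture(scope="session")
def hen_call_model() -> HenCallModel:
    return HenCallModel.from_seed(7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
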