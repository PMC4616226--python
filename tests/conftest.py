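import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lhcswitch import default_registry
from lhcswitch.synthetic import build_synthetic_antenna_complex


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def antenna():
    """The idealized synthetic antenna complex (model, metadata)."""
    return build_synthetic_antenna_complex()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_rotation(rng) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))
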