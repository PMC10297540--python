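import numpy as np
import pytest

from xletseg.image import Image2D
from xletseg.synthetic import PhantomSpec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_image64(rng):
    return Image2D(rng.random((64, 64)))


@pytest.fixture()
def constant_image64():
    return Image2D(np.full((64, 64), 0.43))


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic 64-px phantom with 2-3 cysts."""
    return generate_phantom(PhantomSpec(size=64, cyst_count_range=(2, 3), seed=5))
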