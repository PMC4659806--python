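import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eulerquad import BinaryImage, noise_image

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def img(rows) -> BinaryImage:
    """Shorthand constructor for hand-written fixtures."""
    return BinaryImage(np.asarray(rows, dtype=np.uint8))


@pytest.fixture
def ring3():
    """3x3 ring: one component, one hole, E = 0."""
    return img([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@pytest.fixture
def block2():
    """2x2 solid block, E = 1."""
    return img([[1, 1], [1, 1]])


def random_images(count: int, max_side: int, seed: int):
    """Seeded stream of (image, density) pairs spanning sizes 0..max_side
    and densities 0..1, densities hitting the exact endpoints too."""
    rng = np.random.default_rng(seed)
    for i in range(count):
        h = int(rng.integers(0, max_side + 1))
        w = int(rng.integers(0, max_side + 1))
        if i % 10 == 0:
            density = float(i % 20 == 0)  # exercise the 0 and 1 extremes
        else:
            density = float(rng.random())
        yield noise_image(h, w, density, int(rng.integers(2**31))), density
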