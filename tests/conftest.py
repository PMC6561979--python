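import numpy as np
import pytest


def make_sphere(radius: int, shape: int | None = None, fill_hu: float = -50.0,
                background_hu: float = -800.0):
    """Digital sphere phantom: (volume, mask) with 1 mm isotropic voxels."""
    n = shape or (2 * radius + 11)
    c = (n - 1) / 2
    x, y, z = np.ogrid[:n, :n, :n]
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2
    vol = np.where(mask, fill_hu, background_hu)
    return vol, mask


@pytest.fixture
def sphere10():
    return make_sphere(10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
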