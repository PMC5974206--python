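import numpy as np
import pytest

from punctakit.core import ImageStack
from punctakit.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but realistic synthetic stack shared by several module tests."""
    spec = SyntheticSpec(shape=(15, 256, 256), n_puncta=25, seed=11)
    return generate(spec)


def gaussian_blob_slice(size: int, center: tuple[float, float], sigma: float,
                        peak: float = 100.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center
    return peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


@pytest.fixture
def blob_stack():
    """Single bright Gaussian blob (radius 6 px) at the center of one slice."""
    img = gaussian_blob_slice(64, (32, 32), sigma=3.0)
    return ImageStack(np.round(img[np.newaxis]).astype(np.uint8))
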