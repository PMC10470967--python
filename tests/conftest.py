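import numpy as np
import pytest

from mesr.phantoms import EllipseSpec, rasterize_ellipse_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def disk64():
    """Uniform unit-density disk of radius 0.5, 64 x 64."""
    return rasterize_ellipse_phantom([EllipseSpec(0, 0, 0.5, 0.5, 0, 1.0)], 64)


@pytest.fixture(scope="session")
def disk128():
    return rasterize_ellipse_phantom([EllipseSpec(0, 0, 0.5, 0.5, 0, 1.0)], 128)
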