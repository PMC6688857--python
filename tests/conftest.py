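import numpy as np
import pytest

from photogeo import shading, terrain


@pytest.fixture(scope="session")
def smooth_terrain() -> terrain.HeightField:
    """Band-limited random relief used across contour/covariation tests."""
    return terrain.generate_terrain(seed=1, size=256, cutoff=8)


@pytest.fixture(scope="session")
def rendered_terrain(smooth_terrain):
    """Top-lit Lambertian render of the shared terrain."""
    return shading.render_height_field(smooth_terrain)


@pytest.fixture(scope="session")
def hemisphere():
    """Analytic hemisphere relief (radius 100 px) on a flat plane."""
    n, radius = 256, 100.0
    yy, xx = np.mgrid[0:n, 0:n] - n / 2
    r2 = xx**2 + yy**2
    h = np.where(r2 < radius**2, np.sqrt(np.maximum(radius**2 - r2, 0.0)), 0.0)
    return terrain.HeightField(h), radius
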