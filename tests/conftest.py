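import numpy as np
import pytest

from qlfloss import FluorescenceImage, PolygonROI


@pytest.fixture
def constant_image():
    return FluorescenceImage(np.full((20, 20), 100.0))


@pytest.fixture
def affine_image():
    """L(x, y) = 5 + 2x + 3y on a 20x20 grid."""
    ys, xs = np.mgrid[0:20, 0:20]
    return FluorescenceImage(5.0 + 2.0 * xs + 3.0 * ys)


@pytest.fixture
def quad_roi():
    """A convex quadrilateral comfortably inside a 20x20 image."""
    return PolygonROI(np.array([[3, 3], [16, 4], [15, 15], [4, 14]], dtype=float))


def random_star_polygon(rng, center, r_min, r_max, n_vertices=8):
    """A random star-shaped (hence simple) polygon around ``center``."""
    # one vertex per sector of the circle: strictly increasing angles around
    # the center, so the polygon is star-shaped and therefore simple
    angles = 2 * np.pi * (np.arange(n_vertices) + rng.uniform(0.05, 0.95, n_vertices)) / n_vertices
    radii = rng.uniform(r_min, r_max, n_vertices)
    cx, cy = center
    verts = np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)
    return PolygonROI(verts)
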