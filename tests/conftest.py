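import numpy as np
import pytest

from mlcmargins import AperturePolygon, circle_aperture


@pytest.fixture
def square10() -> AperturePolygon:
    """Axis-aligned 10 x 10 mm square centered on the isocenter."""
    return AperturePolygon(np.array([[-5.0, -5.0], [5.0, -5.0],
                                     [5.0, 5.0], [-5.0, 5.0]]))


@pytest.fixture
def circle50() -> AperturePolygon:
    """5 cm circular reference aperture."""
    return circle_aperture(50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12,
                          scale: float = 20.0) -> AperturePolygon:
    """Convex hull of a random point cloud (simple by construction)."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(0.0, scale / 2.0, size=(n_points, 2))
    hull = ConvexHull(pts)
    return AperturePolygon(pts[hull.vertices])
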