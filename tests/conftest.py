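import numpy as np
import pytest

from ringcal import ColoredPointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_cloud(rng, n, radius, z=0.0, color=(0.2, 0.8, 0.2), units="mm"):
    """Uniform-area sample of a horizontal disk at height z."""
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    t = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.full(n, z)])
    return ColoredPointCloud(pts, np.tile(color, (n, 1)), units)


def annulus_points(rng, n, r_mid, width, z=0.0):
    r = r_mid + width * rng.uniform(-0.5, 0.5, n)
    t = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.full(n, z)])


def sphere_points(rng, n, radius, center=(0.0, 0.0, 0.0)):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v
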