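import numpy as np
import pytest

from bunchmetric.geometry import PointCloud


def sphere_cloud(n=4000, radius=5.0, seed=0, center=(0.0, 0.0, 0.0), normals=True):
    """Uniform samples on a sphere surface with outward normals."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pts = np.asarray(center) + radius * v
    return PointCloud(pts, v if normals else None)


def ball_points(n=100_000, radius=5.0, seed=0):
    """Uniform samples inside a solid ball."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(-radius, radius, (n, 3))
    return p[np.einsum("ij,ij->i", p, p) <= radius * radius]


def unit_cube_mesh():
    """Watertight unit cube: 8 vertices, 12 outward-wound triangles."""
    from bunchmetric.geometry import TriangleMesh

    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0 face (outward -x)
        [4, 6, 7], [4, 7, 5],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return TriangleMesh(v, f)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
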