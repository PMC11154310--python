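import numpy as np
import pytest

from livestock3d.depth import CameraIntrinsics, DepthImage, backproject, triangulate_grid
from livestock3d.meshes import TriMesh


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_triangle():
    return TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])


@pytest.fixture
def tetrahedron():
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
         [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]]
    )
    # outward-wound closed tetrahedron
    f = [[0, 2, 1], [0, 1, 3], [1, 2, 3], [2, 0, 3]]
    return TriMesh(v, f)


def grid_patch(rows: int, cols: int, spacing: float = 0.01) -> TriMesh:
    """Planar (rows x cols)-vertex grid patch triangulated like a depth image."""
    K = CameraIntrinsics(fx=100, fy=100, cx=cols / 2, cy=rows / 2,
                         width=cols, height=rows)
    depth = DepthImage(np.full((rows, cols), 1.0))
    cloud = backproject(depth, K)
    return triangulate_grid(cloud)


@pytest.fixture
def small_grid_mesh():
    return grid_patch(4, 4)


@pytest.fixture(scope="session")
def icosphere():
    import trimesh as tm

    s = tm.creation.icosphere(subdivisions=2, radius=0.5)
    return TriMesh(np.array(s.vertices), np.array(s.faces))
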