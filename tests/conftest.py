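import warnings

import numpy as np
import pytest
import trimesh

from florashape import TriangleMesh

# Open synthetic flowers legitimately trigger the non-watertight volume
# warning throughout the suite; keep test output readable.
warnings.filterwarnings(
    "ignore", message="mesh is not watertight", category=UserWarning
)


@pytest.fixture(scope="session")
def icosphere():
    """Fine unit-sphere mesh centered at the origin."""
    s = trimesh.creation.icosphere(subdivisions=3)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def unit_cube():
    c = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(c.vertices), np.asarray(c.faces))


@pytest.fixture(scope="session")
def regular_tetrahedron():
    """Regular tetrahedron with edge length 1."""
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(8)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
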