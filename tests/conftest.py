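import numpy as np
import pytest

from connexel.model import ConnectivityMatrix, ConnexelSet, SurfaceMesh
from connexel.synthetic import FixtureSpec, make_surface_set

# the three-connexel example file that the .cxls format is defined by
EXAMPLE_CXLS = (
    "125.3 12.0 31.1 145.2 34.3 25.6 0.61\n"
    "146.1 25.9 54.2 135.3 24.4 25.2 0.12\n"
    "156.2 32.8 22.7 154.3 34.5 45.5 0.76\n"
)


@pytest.fixture
def example_cxls_path(tmp_path):
    p = tmp_path / "example.cxls"
    p.write_text(EXAMPLE_CXLS)
    return p


@pytest.fixture
def tetrahedron():
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(verts, faces, "other")


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def surface_set(fixture_spec):
    return make_surface_set(fixture_spec)


@pytest.fixture
def random_connexels():
    rng = np.random.default_rng(42)
    p = rng.uniform(-50, 50, size=(40, 3))
    q = rng.uniform(-50, 50, size=(40, 3))
    v = rng.uniform(-1, 1, size=40)
    return ConnexelSet(p, q, v, "random")


def random_correlation_matrix(rng, n):
    """Gram-matrix correlation: symmetric, unit diagonal, entries in [-1,1]."""
    x = rng.standard_normal((n, n + 5))
    c = np.corrcoef(x)
    c = (c + c.T) / 2  # exact symmetry (corrcoef is only eps-symmetric)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(c, kind="correlation")
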