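import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sbglm import TriangularMesh, build_fem_matrices, make_mesh  # noqa: E402


@pytest.fixture(scope="session")
def grid_mesh():
    """4x4 planar right-triangle grid (16 vertices, 18 faces)."""
    return make_mesh("grid", 4)


@pytest.fixture(scope="session")
def grid_ops(grid_mesh):
    return build_fem_matrices(grid_mesh)


@pytest.fixture(scope="session")
def icosphere_small():
    """Level-1 icosphere, 42 vertices."""
    return make_mesh("icosphere", 1, radius_mm=30.0)


@pytest.fixture(scope="session")
def single_triangle():
    """Unit-side equilateral triangle."""
    return TriangularMesh(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]],
        [[0, 1, 2]],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
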