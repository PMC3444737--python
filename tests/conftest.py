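import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid1d_cloud():
    from efgmep import make_regular_grid

    return make_regular_grid([(0.0, 10.0)], [11])


@pytest.fixture(scope="session")
def grid2d_cloud():
    from efgmep import make_regular_grid

    return make_regular_grid([(-10.0, 10.0)] * 2, [21, 21])


@pytest.fixture(scope="session")
def irregular2d_cloud():
    """Blue-noise cloud on the unit square, dense enough for quadratic MLS."""
    from efgmep import Domain, make_irregular_cloud

    dom = Domain("unit_square", [(0.0, 1.0), (0.0, 1.0)])
    cloud = make_irregular_cloud(dom, 400, min_spacing=0.03, seed=7)
    return cloud, dom


@pytest.fixture(scope="session")
def cube_speed_sweeps():
    """FHN plane-wave speed sweeps for both quadrature orders (shared by the
    stabilization acceptance check and the quadrature-order comparison)."""
    from efgmep.experiments import run_cube3d

    grids = (5, 6, 8, 10, 12)
    return {
        ppa: run_cube3d(grid_counts=grids, points_per_axis=ppa, scenario="isotropic")
        for ppa in (2, 3)
    }
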