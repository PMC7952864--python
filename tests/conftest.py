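import numpy as np
import pytest

from aftractometry.synthetic import PhantomSpec, make_centerline, rasterize_tube
from aftractometry.tract import TractModel


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Default curved phantom: (curve, density volume, ground-truth t volume)."""
    curve = make_centerline(default_spec.curve_control_points)
    density, t_truth = rasterize_tube(curve, default_spec)
    return curve, density, t_truth


@pytest.fixture(scope="session")
def fitted_tract(phantom):
    _, density, _ = phantom
    return TractModel(density).fit()


@pytest.fixture(scope="session")
def straight_tube_spec():
    """A straight tube along +y inside a small grid."""
    return PhantomSpec(
        grid_shape=(25, 47, 25),
        voxel_size_mm=2.0,
        curve_control_points=[(0.0, -40.0, 0.0), (0.0, 0.0, 0.0), (0.0, 40.0, 0.0)],
        tube_radius_mm=4.0,
    )


@pytest.fixture(scope="session")
def straight_tube(straight_tube_spec):
    curve = make_centerline(straight_tube_spec.curve_control_points)
    return rasterize_tube(curve, straight_tube_spec)


def node_values(volume, nodes):
    """Values of a ScalarVolume at (n, 3) voxel indices."""
    return np.asarray(volume.data)[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
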