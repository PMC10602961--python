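import numpy as np
import pytest

from aneuflow import PhantomSpec, make_phantom, make_tree
from aneuflow.hemodynamics import FieldSeries


@pytest.fixture(scope="session")
def poiseuille_phantom():
    return make_phantom(PhantomSpec(kind="poiseuille", n_times=5))


@pytest.fixture(scope="session")
def rotation_phantom():
    return make_phantom(PhantomSpec(kind="rigid_rotation", omega=5.0, n_times=3))


@pytest.fixture(scope="session")
def reversing_phantom():
    return make_phantom(
        PhantomSpec(kind="pulsatile_poiseuille", mean_speed=0.0, pulse_amplitude=0.25)
    )


@pytest.fixture(scope="session")
def sac_phantom():
    return make_phantom(
        PhantomSpec(kind="sac_on_pipe", speed_ratio=0.5, wss_ratio=0.4, n_times=5)
    )


@pytest.fixture(scope="session")
def three_outlet_tree():
    return make_tree([1.0, 2.0, 1.5])


def toy_surface_series(parent_vals, sac_vals, times=(0.0, 1.0)):
    """A minimal FieldSeries whose wall cells carry prescribed constant |WSS|.

    Geometry is a stand-in (unit areas via explicit overrides); only the
    surface arithmetic matters for the shear-metric unit tests.
    """
    parent_vals = np.asarray(parent_vals, float)
    sac_vals = np.asarray(sac_vals, float)
    n = len(parent_vals) + len(sac_vals)
    # one flat tet + dummy triangles; areas overridden to 1
    points = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    tets = np.array([[0, 1, 2, 3]])
    tris = np.tile([0, 1, 2], (n, 1))
    normals = np.tile([0, 0, 1.0], (n, 1))
    times = np.asarray(times, float)
    vel = np.zeros((times.size, 4, 3))
    mags = np.concatenate([parent_vals, sac_vals])
    wss = np.zeros((times.size, n, 3))
    wss[:, :, 0] = mags[None, :]
    series = FieldSeries(
        points=points, tets=tets, surface_tris=tris, surface_normals=normals,
        times=times, velocity=vel, wss=wss,
        cell_volumes=np.ones(1), surface_areas=np.ones(n),
    )
    parent_idx = np.arange(len(parent_vals))
    sac_idx = np.arange(len(parent_vals), n)
    return series, parent_idx, sac_idx
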