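import math

import numpy as np
import pytest

import tigon as tg


@pytest.fixture(scope="session")
def uniform_mesh():
    """8x8 hexagonal mesh realized from a uniform tension triangulation."""
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=8, ny=8, pattern="uniform")
    )
    mesh, gt = tg.realize_mesh_from_tensions(tri, l0=4.2)
    return mesh, gt


@pytest.fixture(scope="session")
def random_mesh():
    """Irregular mesh from a random Delaunay tension triangulation."""
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=7, ny=7, pattern="random", seed=3)
    )
    mesh, gt = tg.realize_mesh_from_tensions(tri, l0=4.2)
    return mesh, gt


@pytest.fixture(scope="session")
def active_sequence():
    """Tracked sequence with one programmed active T1."""
    return tg.generate_t1_sequence("active", nx=7, ny=7, seed=1)


@pytest.fixture(scope="session")
def passive_sequence():
    """Tracked sequence with one programmed passive T1."""
    return tg.generate_t1_sequence("passive", nx=7, ny=7, seed=2)


def square_threshold_mesh(arm: float = 2.0, h: float = 1.0):
    """Four cells around a vertical interface whose end vertices both read
    vertex angles (90, 135, 135) — the square threshold configuration."""
    u = np.array([0.0, h])
    v = np.array([0.0, -h])
    c45 = arm / math.sqrt(2)
    ur = u + [c45, c45]
    ul = u + [-c45, c45]
    lr = v + [c45, -c45]
    ll = v + [-c45, -c45]
    loops = {
        1: [v, u, ul, ll],        # left cell
        2: [u, v, lr, ur],        # right cell
        3: [u, ur, np.array([0.0, h + arm]), ul],   # top cell
        4: [v, ll, np.array([0.0, -h - arm]), lr],  # bottom cell
    }
    return tg.mesh_from_cells(loops)


@pytest.fixture()
def square_mesh():
    return square_threshold_mesh()
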