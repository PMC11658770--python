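"""Tension-isogonal decomposition: recovery, aspect conventions, fields."""

import math

import numpy as np
import pandas as pd
import pytest

import tigon as tg
from tigon.isogonal import IsogonalTensor

SQRT3 = math.sqrt(3)
L0 = 4.2


def _reference_triangle():
    """A tension triangle in physical orientation (arbitrary pose)."""
    return np.array([[0.0, 0.0], [1.1, 0.2], [0.4, 0.9]])


def test_vertex_isogonal_identity():
    t = _reference_triangle()
    tensor = tg.vertex_isogonal(t, L0 * t, l0=L0)
    np.testing.assert_allclose(tensor.matrix, np.eye(2), atol=1e-12)


@pytest.mark.parametrize(
    "A",
    [
        np.diag([1.2, 1 / 1.2]),
        np.array([[1.1, 0.3], [-0.2, 0.9]]),
        np.array([[math.cos(0.4), -math.sin(0.4)],
                  [math.sin(0.4), math.cos(0.4)]]),
    ],
)
def test_vertex_isogonal_recovers_applied_map(A):
    t = _reference_triangle()
    tensor = tg.vertex_isogonal(t, (L0 * t) @ A.T, l0=L0)
    np.testing.assert_allclose(tensor.matrix, A, atol=1e-12)


def test_vertex_isogonal_rotation_has_unit_aspect():
    th = 0.9
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    t = _reference_triangle()
    tensor = tg.vertex_isogonal(t, (L0 * t) @ R.T, l0=L0)
    assert tensor.aspect_ratio == pytest.approx(1.0, abs=1e-12)
    # polar decomposition isolates the rotation
    rot, stretch = tensor.polar_parts()
    np.testing.assert_allclose(stretch, np.eye(2), atol=1e-12)
    np.testing.assert_allclose(rot, R, atol=1e-12)


def test_vertex_isogonal_degenerate_triangle_errors():
    t = np.array([[0, 0], [1, 0], [2, 0.0]])
    with pytest.raises(ValueError):
        tg.vertex_isogonal(t, t * L0, l0=L0)


def test_quartet_isogonal_identity_and_recovery():
    edges = tg.passive_collapse_quartet(1.0, l0=L0)
    tensor = tg.quartet_isogonal(edges, l0=L0)
    np.testing.assert_allclose(tensor.matrix, np.eye(2), atol=1e-12)
    assert tensor.residual < 1e-12
    A = np.diag([1.2, 1 / 1.2])
    edges2 = [(tv, A @ dc) for tv, dc in edges]
    t2 = tg.quartet_isogonal(edges2, l0=L0)
    np.testing.assert_allclose(t2.matrix, A, atol=1e-10)


def test_quartet_isogonal_noise_bias_bounded():
    """Centroid noise at 5% of edge length leaves the mean recovered
    stretch within 2% of truth over 100 seeds."""
    A = np.diag([1.2, 1 / 1.2])
    edges = tg.passive_collapse_quartet(1.0, l0=L0)
    scale = np.mean([np.linalg.norm(dc) for _, dc in edges])
    recovered = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        noisy = [
            (tv, A @ dc + 0.05 * scale * rng.standard_normal(2))
            for tv, dc in edges
        ]
        recovered.append(tg.quartet_isogonal(noisy, l0=L0).stretch)
    mean = np.mean(recovered, axis=0)
    assert abs(mean[0, 0] - 1.2) < 0.02 * 1.2
    assert abs(mean[1, 1] - 1 / 1.2) < 0.02 / 1.2


def test_quartet_isogonal_composition():
    A = np.array([[1.15, 0.1], [0.0, 0.9]])
    B = np.array([[0.95, -0.05], [0.1, 1.1]])
    edges = tg.passive_collapse_quartet(1.0, l0=L0)
    composed = [(tv, (A @ B) @ dc) for tv, dc in edges]
    t = tg.quartet_isogonal(composed, l0=L0)
    np.testing.assert_allclose(t.matrix, A @ B, atol=1e-10)


def test_quartet_isogonal_rank_deficient_errors():
    tv = np.array([1.0, 0.0])
    with pytest.raises(ValueError):
        tg.quartet_isogonal([(tv, tv), (tv, tv), (tv, tv)], l0=L0)


def test_mesh_level_recovery_of_applied_map(uniform_mesh):
    """The applied isogonal map is recovered (up to the tension-gauge
    scale) at every interior vertex and quartet of a realized mesh."""
    A = np.diag([1.2, 1 / 1.2])
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=8, ny=8, pattern="uniform")
    )
    mesh, _ = tg.realize_mesh_from_tensions(tri, l0=L0, isogonal=A)
    table = tg.vertex_isogonal_table(mesh, l0=L0)
    assert len(table) > 30
    for row in table.itertuples():
        I = IsogonalTensor(np.array([[row.Ixx, row.Ixy],
                                     [row.Iyx, row.Iyy]]))
        np.testing.assert_allclose(I.unimodular, A, atol=1e-10)
    n_q = 0
    for eid in mesh.interfaces:
        try:
            t = tg.quartet_isogonal_of_edge(mesh, eid, l0=L0)
        except Exception:
            continue
        np.testing.assert_allclose(t.unimodular, A, atol=1e-10)
        n_q += 1
    assert n_q > 30


def test_quartet_shape_aspect_conventions():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
    assert tg.quartet_shape_aspect(square) == pytest.approx(1.0)
    assert tg.quartet_shape_aspect(
        square @ np.diag([2.0, 1.0])
    ) == pytest.approx(2.0, abs=1e-12)
    assert math.isinf(
        tg.quartet_shape_aspect(np.array([[0, 0], [1, 1], [2, 2.0]]))
    )


def test_passive_collapse_aspect_is_sqrt3():
    """The symmetric passive collapse (120-degree angles kept, central
    edge shrunk to zero from the hexagonal reference) accumulates an
    isogonal aspect ratio of sqrt(3)."""
    tensor = tg.quartet_isogonal(tg.passive_collapse_quartet(0.0), l0=L0)
    assert tensor.aspect_ratio == pytest.approx(SQRT3, abs=1e-9)
    # and the aspect grows monotonically along the collapse
    aspects = [
        tg.quartet_isogonal(tg.passive_collapse_quartet(f), l0=L0).aspect_ratio
        for f in (1.0, 0.6, 0.3, 0.0)
    ]
    assert all(b > a - 1e-12 for a, b in zip(aspects, aspects[1:]))


def test_edge_decomposition_zero_on_reference_mesh(uniform_mesh):
    mesh, _ = uniform_mesh
    n = 0
    for eid, itf in mesh.interfaces.items():
        if itf.is_boundary:
            continue
        try:
            lref, dliso = tg.edge_length_decomposition(mesh, eid, l0=L0)
        except Exception:
            continue
        assert lref == pytest.approx(mesh.interface_length(eid), abs=1e-9)
        assert dliso == pytest.approx(0.0, abs=1e-9)
        n += 1
    assert n > 20


def test_edge_decomposition_pure_isogonal_stretch():
    """Stretching the DV interfaces by 1.2 at fixed angles leaves l_ref
    unchanged, so dl_iso = 0.2 * l_ref on those interfaces."""
    from tigon.synth import _honeycomb
    from tigon.mesh import mesh_from_cells

    l_h = L0 / SQRT3
    centers, offsets, _ = _honeycomb(6, 6, 1.2 * l_h, l_h)
    loops = {
        j * 6 + i: [c + np.array(o) for o in offsets]
        for (i, j), c in centers.items()
    }
    mesh = mesh_from_cells(loops)
    checked = 0
    for eid, itf in mesh.interfaces.items():
        if itf.is_boundary:
            continue
        vec = mesh.interface_vector(eid)
        if abs(vec[0]) > 1e-9:  # only the stretched vertical interfaces
            continue
        try:
            lref, dliso = tg.edge_length_decomposition(mesh, eid, l0=L0)
        except Exception:
            continue
        assert dliso == pytest.approx(0.2 * lref, rel=1e-9)
        checked += 1
    assert checked > 4


def test_edge_decomposition_at_exchange_equals_minus_lref():
    """At the neighbor exchange (l = 0) the isogonal length equals
    -l_ref (simulated passive trajectory)."""
    from tigon.quartet import ModelParams, dl_iso_of_state, simulate_passive
    from tigon.geometry import TensionKite

    params = ModelParams()
    traj = simulate_passive(params, t_max=20.0)
    last = traj.pre_flip()[-1]
    kite = TensionKite(shared=last.t_rel, left=(1, 1), right=(1, 1))
    lref = tg.voronoi_reference_length(kite, l0=params.l0)
    assert dl_iso_of_state(last, params) == pytest.approx(
        -lref, abs=0.02 * params.l0
    )


def test_grid_average_isogonal_identity_and_uniform():
    rows = []
    for i, (x, y) in enumerate([(1, 1), (5, 8), (30, 2), (25, 25)]):
        rows.append(
            {"x": x, "y": y, "Ixx": 1.0, "Ixy": 0.0, "Iyx": 0.0,
             "Iyy": 1.3}
        )
    out = tg.grid_average_isogonal(pd.DataFrame(rows), spacing=20.0)
    np.testing.assert_allclose(out.dvdv, 1.3, atol=1e-12)
    np.testing.assert_allclose(out.s1, 1.3, atol=1e-12)
    np.testing.assert_allclose(out.s2, 1.0, atol=1e-12)


def test_grid_average_isogonal_mixes_populations():
    rows = [
        {"x": 1.0, "y": 1.0, "Ixx": 1.0, "Ixy": 0, "Iyx": 0, "Iyy": 1.0},
        {"x": 2.0, "y": 2.0, "Ixx": 1.0, "Ixy": 0, "Iyx": 0, "Iyy": 1.4},
    ]
    out = tg.grid_average_isogonal(pd.DataFrame(rows), spacing=10.0)
    assert len(out) == 1
    assert out.dvdv.iloc[0] == pytest.approx(1.2, abs=1e-12)
    assert out["count"].iloc[0] == 2


def test_calibrate_l0_hexagonal_duality(uniform_mesh):
    mesh, _ = uniform_mesh
    lengths = [
        mesh.interface_length(e)
        for e, i in mesh.interfaces.items()
        if not i.is_boundary
    ]
    assert tg.calibrate_l0(mesh) == pytest.approx(
        SQRT3 * np.mean(lengths), rel=1e-6
    )
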