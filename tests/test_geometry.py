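"""Tension-space geometry: triangles, kites, T1 threshold, LTC shapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tigon as tg
from tigon.geometry import ForceBalanceError, TensionKite

SQRT2, SQRT3 = math.sqrt(2), math.sqrt(3)


@pytest.mark.parametrize(
    "sides, angles_deg",
    [
        ((1, 1, 1), (60, 60, 60)),
        ((SQRT3, 1, 1), (120, 30, 30)),
        ((SQRT2, 1, 1), (90, 45, 45)),
    ],
)
def test_triangle_landmarks(sides, angles_deg):
    tri = tg.triangle_from_tensions(*sides)
    np.testing.assert_allclose(np.degrees(tri.angles), angles_deg,
                               atol=1e-9)
    np.testing.assert_allclose(
        np.degrees(tri.dual_vertex_angles), 180 - np.array(angles_deg),
        atol=1e-9,
    )
    assert tri.angles.sum() == pytest.approx(math.pi, abs=1e-12)


def test_triangle_inequality_enforced():
    with pytest.raises(ForceBalanceError):
        tg.triangle_from_tensions(2.5, 1, 1)
    with pytest.raises(ForceBalanceError):
        tg.triangle_from_tensions(-1, 1, 1)


def test_reference_length_equilateral():
    kite = TensionKite(shared=1.0, left=(1, 1), right=(1, 1))
    # two unit equilateral triangles: circumcenter distance = cot(60)
    assert tg.voronoi_reference_length(kite, l0=1.0) == pytest.approx(
        1 / SQRT3, abs=1e-12
    )


@pytest.mark.parametrize(
    "phi_deg, sign",
    [(60.0, 1), (89.9, 1), (90.0, 0), (90.1, -1), (120.0, -1)],
)
def test_reference_length_sign_through_threshold(phi_deg, sign):
    """l_ref vanishes at the concyclic (square) configuration and turns
    negative past it."""
    phi = math.radians(phi_deg)
    t = 2 * math.sin(phi / 2)
    kite = TensionKite(shared=t, left=(1, 1), right=(1, 1))
    lref = tg.voronoi_reference_length(kite, l0=1.0)
    if sign == 0:
        assert lref == pytest.approx(0.0, abs=1e-12)
    else:
        assert math.copysign(1, lref) == sign
    # symmetric closed form l0 * T * cot(phi)
    assert lref == pytest.approx(t / math.tan(phi), abs=1e-12)


def test_reference_length_zero_iff_concyclic():
    """Signed circumcenter distance vanishes exactly when the four kite
    corners are concyclic (independent circumcircle oracle)."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        # place 4 points on a common circle -> concyclic kite
        r = rng.uniform(0.5, 2.0)
        th = np.sort(rng.uniform(0, 2 * math.pi, 4))
        pts = r * np.stack([np.cos(th), np.sin(th)], axis=1)
        A, B, C, D = pts[0], pts[2], pts[1], pts[3]  # diagonal AB
        kite = TensionKite(
            shared=float(np.linalg.norm(B - A)),
            left=(float(np.linalg.norm(C - A)),
                  float(np.linalg.norm(C - B))),
            right=(float(np.linalg.norm(D - A)),
                   float(np.linalg.norm(D - B))),
        )
        assert tg.voronoi_reference_length(kite, 1.0) == pytest.approx(
            0.0, abs=1e-9
        )


def test_t1_threshold_at_zero_is_sqrt2():
    assert tg.t1_threshold(0.0, l0=4.2) == pytest.approx(SQRT2, abs=1e-10)


def test_t1_threshold_unity_at_hexagonal_contraction():
    """Isogonal contraction by the full hexagonal reference length brings
    the threshold down to 1 (phi = 60 solves the relation identically)."""
    l0 = 4.2
    assert tg.t1_threshold(-l0 / SQRT3, l0=l0) == pytest.approx(1.0,
                                                               abs=1e-9)


def test_t1_threshold_monotone_increasing():
    l0 = 4.2
    dl = np.linspace(-2.0, 3.0, 41)
    tc = np.array([tg.t1_threshold(d, l0) for d in dl])
    assert np.all(np.diff(tc) > 0)
    assert np.all(tc[dl > 0] > SQRT2)


def test_t1_threshold_out_of_range():
    with pytest.raises(ValueError):
        tg.t1_threshold(-5.0, l0=4.2)


def test_flip_equilateral_kite_gives_sqrt3():
    kite = TensionKite(shared=1.0, left=(1, 1), right=(1, 1))
    assert tg.flip_kite(kite).shared == pytest.approx(SQRT3, abs=1e-12)


def test_flip_square_kite_self_dual():
    kite = TensionKite(shared=SQRT2, left=(1, 1), right=(1, 1))
    assert tg.flip_kite(kite).shared == pytest.approx(SQRT2, abs=1e-12)


def test_flip_is_involution_on_random_convex_kites():
    rng = np.random.default_rng(7)
    n_ok = 0
    while n_ok < 30:
        shared = rng.uniform(0.5, 1.5)
        left = tuple(rng.uniform(0.6, 1.6, 2))
        right = tuple(rng.uniform(0.6, 1.6, 2))
        kite = TensionKite(shared=shared, left=left, right=right)
        try:
            flipped = tg.flip_kite(kite)
            back = tg.flip_kite(flipped)
        except ForceBalanceError:
            continue
        assert back.shared == pytest.approx(shared, rel=1e-9)
        n_ok += 1


def test_flip_nonconvex_errors():
    # apexes far off to one side: diagonals do not cross
    kite = TensionKite(shared=1.0, left=(0.55, 1.5), right=(0.55, 1.5))
    with pytest.raises(ForceBalanceError):
        tg.flip_kite(kite)


@pytest.mark.parametrize(
    "sides, a_expected, b_expected",
    [
        ((1, 1, 1), 0.0, -0.5),
        ((1, 1, SQRT2), None, 0.0),
        ((SQRT3, 1, 1), None, 0.5),
    ],
)
def test_ltc_shape_landmarks(sides, a_expected, b_expected):
    sh = tg.ltc_shape(sides)
    if a_expected is not None:
        assert sh.a == pytest.approx(a_expected, abs=1e-9)
    assert sh.b == pytest.approx(b_expected, abs=1e-9)


def test_ltc_shape_obtuse_isosceles_elongation_oracle():
    """Elongation of the (sqrt3,1,1) triangle against an explicit
    gyration-tensor computation."""
    pts = np.array([[0, 0], [SQRT3, 0],
                    [SQRT3 / 2, 0.5]])  # sides sqrt3, 1, 1
    g = np.cov(pts.T, bias=True)
    lam = np.sort(np.linalg.eigvalsh(g))[::-1]
    a_oracle = (math.sqrt(lam[0]) - math.sqrt(lam[1])) / (
        math.sqrt(lam[0]) + math.sqrt(lam[1])
    )
    sh = tg.ltc_shape((SQRT3, 1, 1))
    assert sh.a == pytest.approx(a_oracle, abs=1e-9)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    sides=st.tuples(
        st.floats(0.5, 2.0), st.floats(0.5, 2.0), st.floats(0.5, 2.0)
    ),
    scale=st.floats(0.1, 10.0),
    perm=st.permutations([0, 1, 2]),
)
def test_ltc_shape_similarity_and_relabel_invariance(sides, scale, perm):
    s = np.sort(sides)
    if s[0] + s[1] <= s[2] * 1.001:
        return
    base = tg.ltc_shape(tuple(sides))
    other = tg.ltc_shape(tuple(scale * np.array(sides)[list(perm)]))
    assert other.a == pytest.approx(base.a, abs=1e-8)
    assert other.b == pytest.approx(base.b, abs=1e-8)


def test_ltc_statistics_uniform_lattice():
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=8, ny=8, pattern="uniform")
    )
    stats = tri.ltc_statistics()
    assert stats["bridge_fraction"] == 0.0
    assert stats["median_b"] == pytest.approx(-0.5, abs=1e-9)
    np.testing.assert_allclose(stats["a"], 0.0, atol=1e-9)


def test_ltc_statistics_bridge_pattern_all_obtuse():
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=10, ny=10, pattern="alternating_bridge",
                         eps=0.3)
    )
    stats = tri.ltc_statistics()
    assert stats["bridge_fraction"] == 1.0
    assert stats["median_b"] > 0


def test_ltc_statistics_cable_pattern_all_acute():
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=10, ny=10, pattern="cable", eps=0.3)
    )
    stats = tri.ltc_statistics()
    assert stats["bridge_fraction"] == 0.0


def test_ltc_statistics_empty_region_errors():
    with pytest.raises(ValueError):
        tg.ltc_statistics(np.empty((0, 3)))


def test_random_delaunay_baseline_deterministic():
    a = tg.random_delaunay_baseline(500, seed=9)
    b = tg.random_delaunay_baseline(500, seed=9)
    assert a["bridge_fraction"] == b["bridge_fraction"]
    np.testing.assert_array_equal(a["hist"], b["hist"])


def test_random_delaunay_baseline_stable_across_seeds():
    fracs = [
        tg.random_delaunay_baseline(2000, seed=s)["bridge_fraction"]
        for s in range(10)
    ]
    assert np.std(fracs) < 0.03
    meds = [
        tg.random_delaunay_baseline(2000, seed=s)["median_b"]
        for s in range(10)
    ]
    assert np.std(meds) < 0.02


def test_baseline_separates_from_ordered_lattice():
    from scipy.stats import ks_2samp

    base = tg.random_delaunay_baseline(2000, seed=1)
    tri = tg.make_tension_triangulation(
        tg.GeneratorSpec(nx=20, ny=20, pattern="uniform")
    )
    lattice = tri.ltc_statistics()
    stat = ks_2samp(base["b"], lattice["b"]).statistic
    assert stat > 0.5
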