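"""Tension-space geometry.

At force balance, the three cortical tensions pulling on a tri-cellular
vertex close into a *tension triangle* whose internal angles are
complementary to the vertex angles (they sum pairwise to 180 degrees).
Across a cell-cell interface the two end-vertex triangles share the side
dual to that interface, forming a *kite*.  The Voronoi construction on the
tension triangulation assigns each interface a reference length
``l_ref = l0 * (T/2) * (cot(phi_left) + cot(phi_right))`` (signed distance
between the two circumcenters, scaled by ``l0``), which for a symmetric
kite reduces to ``l0 * T * cot(phi)``.  Setting the observed length
``l = l_ref + dl_iso`` to zero defines the T1 threshold: at zero isogonal
length the critical relative tension is sqrt(2).

The module also provides the local-tension-configuration (LTC) shape
coordinates of a tension triangle — elongation ``a`` and the
bridge-vs-cable parameter ``b = -cos(theta_max)`` — and the random-Delaunay
disorder baseline for their statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay

__all__ = [
    "TensionTriangle",
    "TensionKite",
    "LTCShape",
    "ThresholdCurve",
    "triangle_from_tensions",
    "voronoi_reference_length",
    "t1_threshold",
    "threshold_curve",
    "flip_kite",
    "ltc_shape",
    "ltc_statistics",
    "random_delaunay_baseline",
    "DEFAULT_L0",
    "DEFAULT_MEAN_INITIAL_LENGTH",
]

#: Tension-to-length scale (um) converting relative tensions to physical
#: interface lengths through the Voronoi reference construction.
DEFAULT_L0 = 4.2

#: Mean interface length (um) of the resting cell array the scale is
#: calibrated against.
DEFAULT_MEAN_INITIAL_LENGTH = 3.5


class ForceBalanceError(ValueError):
    """Tensions admit no closed triangle (no force-balanced configuration)."""


@dataclass(frozen=True)
class TensionTriangle:
    """Triangle whose side lengths are the three relative tensions.

    ``angles[i]`` is the internal angle opposite side ``tensions[i]``;
    the dual vertex angle between the other two interfaces is
    ``pi - angles[i]``.
    """

    tensions: tuple[float, float, float]
    vertex_id: int | None = None

    @property
    def angles(self) -> np.ndarray:
        return _internal_angles(np.asarray(self.tensions, dtype=float))

    @property
    def dual_vertex_angles(self) -> np.ndarray:
        return math.pi - self.angles

    @property
    def is_degenerate(self) -> bool:
        t = sorted(self.tensions)
        return t[0] + t[1] <= t[2] * (1 + 1e-12)

    def points(self) -> np.ndarray:
        """An embedding of the triangle: vertex i is opposite side i."""
        t0, t1, t2 = self.tensions
        # vertex 0 opposite side 0: place side 0 from origin along x
        p1 = np.array([0.0, 0.0])
        p2 = np.array([t0, 0.0])
        a = self.angles  # angle at vertex 1 is a[1]
        p0 = p1 + t2 * np.array([math.cos(a[1]), math.sin(a[1])])
        return np.stack([p0, p1, p2])


@dataclass(frozen=True)
class TensionKite:
    """Two tension triangles adjoined along the side dual to one interface.

    ``shared`` is the tension on the central interface; ``left`` and
    ``right`` are the remaining two sides of each triangle, ordered
    (side at first shared-side endpoint, side at second endpoint).
    """

    shared: float
    left: tuple[float, float]
    right: tuple[float, float]
    edge_id: int | None = None

    @property
    def apex_angles(self) -> tuple[float, float]:
        """Angles opposite the shared side in the two triangles."""
        return (
            _opposite_angle(self.shared, *self.left),
            _opposite_angle(self.shared, *self.right),
        )

    def triangles(self) -> tuple[TensionTriangle, TensionTriangle]:
        return (
            TensionTriangle((self.shared, *self.left)),
            TensionTriangle((self.shared, *self.right)),
        )

    def points(self) -> np.ndarray:
        """Embed the kite: shared side on the x-axis, apexes above/below.

        Returns (A, B, C, D): shared side A->B, left apex C (y > 0),
        right apex D (y < 0).
        """
        T = self.shared
        A = np.array([-T / 2, 0.0])
        B = np.array([T / 2, 0.0])
        C = _apex(A, B, self.left[0], self.left[1], up=True)
        D = _apex(A, B, self.right[0], self.right[1], up=False)
        return np.stack([A, B, C, D])


@dataclass(frozen=True)
class LTCShape:
    """Shape coordinates of a tension triangle.

    ``a`` in [0, 1): elongation (0 = equilateral, -> 1 degenerate);
    ``b`` in (-0.5, 1]: -cos of the largest internal angle; b > 0 marks
    obtuse (bridge) configurations, b < 0 acute (cable) ones.
    """

    a: float
    b: float
    theta_max: float
    degenerate: bool = False


def triangle_from_tensions(t0: float, t1: float, t2: float) -> TensionTriangle:
    """Build a tension triangle, checking the strict triangle inequality.

    Raises :class:`ForceBalanceError` if the three tensions cannot close
    into a triangle (no force-balanced vertex exists).
    """
    t = np.array([t0, t1, t2], dtype=float)
    if np.any(t <= 0):
        raise ForceBalanceError(f"non-positive tension in {tuple(t)}")
    s = np.sort(t)
    if s[0] + s[1] <= s[2]:
        raise ForceBalanceError(
            f"tensions {tuple(t)} violate the strict triangle inequality"
        )
    return TensionTriangle((float(t0), float(t1), float(t2)))


def voronoi_reference_length(kite: TensionKite, l0: float = DEFAULT_L0) -> float:
    """Signed Voronoi reference length of the kite's central interface.

    The reference length is ``l0`` times the signed distance between the
    circumcenters of the two tension triangles:
    ``l_ref = l0 * (T/2) * (cot(phi_left) + cot(phi_right))``, positive for
    a valid Voronoi edge, zero when the four kite corners are concyclic and
    negative past the flip.  In the symmetric case this is the closed form
    ``l0 * T * cot(phi)``.
    """
    for tri in kite.triangles():
        if tri.is_degenerate:
            raise ForceBalanceError("degenerate tension triangle in kite")
    phi_l, phi_r = kite.apex_angles
    return l0 * (kite.shared / 2.0) * (1 / math.tan(phi_l) + 1 / math.tan(phi_r))


def t1_threshold(dl_iso: float, l0: float = DEFAULT_L0) -> float:
    """Critical relative tension of a symmetric quartet at isogonal length
    ``dl_iso``.

    Solves ``l0 * T * cot(phi) + dl_iso = 0`` with ``T = 2 sin(phi/2)``
    (equivalently ``l0 * cos(phi)/cos(phi/2) = -dl_iso``) by bracketed
    root-finding on the apex angle ``phi`` in (0, pi); returns
    ``T_crit = 2 sin(phi/2)``, which is sqrt(2) at ``dl_iso = 0``.

    A root exists for ``dl_iso > -l0`` (the reference length of a symmetric
    kite is bounded above by ``l0``).
    """
    if l0 <= 0:
        raise ValueError("l0 must be positive")
    if dl_iso <= -l0:
        raise ValueError(
            f"no threshold: dl_iso = {dl_iso} <= -l0 = {-l0} "
            "(reference length cannot exceed l0)"
        )

    def f(phi: float) -> float:
        return l0 * math.cos(phi) / math.cos(phi / 2) + dl_iso

    lo, hi = 1e-12, math.pi - 1e-9
    phi = brentq(f, lo, hi, xtol=1e-12)
    t = 2.0 * math.sin(phi / 2)
    if not 0.0 < t < 2.0:
        raise ValueError(f"threshold tension {t} out of range (0, 2)")
    return t


@dataclass
class ThresholdCurve:
    """Sampled T1-threshold curve T_crit(dl_iso) at a fixed scale l0."""

    l0: float
    dl_iso: np.ndarray
    t_crit: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"dl_iso_um": self.dl_iso, "T_crit": self.t_crit})


def threshold_curve(
    dl_min: float, dl_max: float, step: float, l0: float = DEFAULT_L0
) -> ThresholdCurve:
    dl = np.arange(dl_min, dl_max + 0.5 * step, step)
    t = np.array([t1_threshold(d, l0) for d in dl])
    return ThresholdCurve(l0, dl, t)


def flip_kite(kite: TensionKite) -> TensionKite:
    """Edge flip of the kite: the new shared side is the other diagonal of
    the tension quadrilateral; the four outer sides are unchanged.

    Models the neighbor exchange: the interface dual to the shared side
    collapses, and the tension on the emerging interface is fixed by the
    geometry of the flipped triangulation.  Requires the quadrilateral to
    be convex (the two diagonals must cross), else the flip is undefined.
    """
    A, B, C, D = kite.points()
    # diagonals AB and CD must intersect strictly inside
    denom = C[1] - D[1]
    if denom <= 0:
        raise ForceBalanceError("flip undefined: apexes on the same side")
    x_cross = D[0] + (C[0] - D[0]) * (-D[1]) / denom
    if not (A[0] < x_cross < B[0]):
        raise ForceBalanceError(
            "flip undefined: tension quadrilateral is not convex"
        )
    new_shared = float(np.linalg.norm(C - D))
    # new triangles: (CD, CA, DA) with apex A and (CD, CB, DB) with apex B
    return TensionKite(
        shared=new_shared,
        left=(float(np.linalg.norm(C - A)), float(np.linalg.norm(D - A))),
        right=(float(np.linalg.norm(C - B)), float(np.linalg.norm(D - B))),
    )


def ltc_shape(triangle: TensionTriangle | tuple[float, float, float]) -> LTCShape:
    """LTC shape coordinates (a, b) of a tension triangle.

    ``a = (sqrt(l1) - sqrt(l2)) / (sqrt(l1) + sqrt(l2))`` from the
    eigenvalues ``l1 >= l2`` of the gyration tensor of the three triangle
    vertices; ``b = -cos(theta_max)``.  Both are invariant under rotation,
    translation, uniform scaling and relabeling of the vertices.
    """
    if not isinstance(triangle, TensionTriangle):
        triangle = TensionTriangle(tuple(float(x) for x in triangle))
    if triangle.is_degenerate:
        return LTCShape(a=1.0, b=1.0, theta_max=math.pi, degenerate=True)
    pts = triangle.points()
    g = np.cov(pts.T, bias=True)
    lam = np.sort(np.linalg.eigvalsh(g))[::-1]
    lam = np.clip(lam, 0.0, None)
    r1, r2 = math.sqrt(lam[0]), math.sqrt(lam[1])
    a = (r1 - r2) / (r1 + r2)
    theta_max = float(np.max(triangle.angles))
    return LTCShape(a=float(a), b=-math.cos(theta_max), theta_max=theta_max)


def ltc_statistics(
    sides: np.ndarray,
    bins: int = 20,
    a_range: tuple[float, float] = (0.0, 1.0),
    b_range: tuple[float, float] = (-0.5, 1.0),
) -> dict:
    """LTC summary statistics for a set of tension triangles.

    Parameters
    ----------
    sides
        (N, 3) array of triangle side lengths (relative tensions).

    Returns
    -------
    dict with keys ``a``, ``b`` (per-triangle arrays), ``hist``
    (2D histogram over (a, b)), ``a_edges``, ``b_edges``,
    ``bridge_fraction`` (fraction of triangles with b > 0), ``median_b``
    and ``n``.
    """
    sides = np.atleast_2d(np.asarray(sides, dtype=float))
    if len(sides) == 0:
        raise ValueError("no triangles in region")
    shapes = [ltc_shape(tuple(s)) for s in sides]
    a = np.array([s.a for s in shapes])
    b = np.array([s.b for s in shapes])
    hist, a_edges, b_edges = np.histogram2d(
        a, b, bins=bins, range=[a_range, b_range]
    )
    return {
        "a": a,
        "b": b,
        "hist": hist,
        "a_edges": a_edges,
        "b_edges": b_edges,
        "bridge_fraction": float(np.mean(b > 0)),
        "median_b": float(np.median(b)),
        "n": len(a),
    }


def ltc_statistics_from_vertex_tensions(vertex_df, bins: int = 20) -> dict:
    """LTC statistics from a per-vertex tension table (columns T0, T1, T2)."""
    sides = vertex_df[["T0", "T1", "T2"]].to_numpy(dtype=float)
    return ltc_statistics(sides, bins=bins)


def random_delaunay_baseline(
    n_points: int, seed: int, bins: int = 20
) -> dict:
    """LTC statistics of the Delaunay triangulation of uniform random points.

    The disorder baseline the observed shape distribution is compared
    against.  Triangles with a vertex on the convex hull are excluded;
    the output is fully determined by ``seed``.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    rng = np.random.default_rng(seed)
    pts = rng.random((n_points, 2))
    tri = Delaunay(pts)
    hull = set(tri.convex_hull.ravel().tolist())
    keep = [s for s in tri.simplices if not (set(s.tolist()) & hull)]
    sides = np.array(
        [
            [
                np.linalg.norm(pts[s[0]] - pts[s[1]]),
                np.linalg.norm(pts[s[1]] - pts[s[2]]),
                np.linalg.norm(pts[s[2]] - pts[s[0]]),
            ]
            for s in keep
        ]
    )
    return ltc_statistics(sides, bins=bins)


# ------------------------------------------------------------------ helpers


def _internal_angles(sides: np.ndarray) -> np.ndarray:
    """Internal angles opposite each side, by the law of cosines."""
    a, b, c = sides
    s = np.sort(sides)
    if s[0] + s[1] <= s[2]:
        raise ForceBalanceError(
            f"side lengths {tuple(sides)} violate the triangle inequality"
        )
    return np.array(
        [
            math.acos(np.clip((b * b + c * c - a * a) / (2 * b * c), -1, 1)),
            math.acos(np.clip((a * a + c * c - b * b) / (2 * a * c), -1, 1)),
            math.acos(np.clip((a * a + b * b - c * c) / (2 * a * b), -1, 1)),
        ]
    )


def _opposite_angle(opp: float, s1: float, s2: float) -> float:
    return math.acos(np.clip((s1 * s1 + s2 * s2 - opp * opp) / (2 * s1 * s2), -1, 1))


def _apex(A: np.ndarray, B: np.ndarray, rA: float, rB: float, up: bool) -> np.ndarray:
    """Apex at distance rA from A and rB from B, above or below segment AB."""
    d = float(np.linalg.norm(B - A))
    x = (rA * rA - rB * rB + d * d) / (2 * d)
    h2 = rA * rA - x * x
    if h2 < -1e-12 * max(rA, rB) ** 2:
        raise ForceBalanceError("kite sides violate the triangle inequality")
    h = math.sqrt(max(h2, 0.0))
    e = (B - A) / d
    n = np.array([-e[1], e[0]])
    return A + x * e + (h if up else -h) * n
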