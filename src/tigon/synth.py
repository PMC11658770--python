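"""Synthetic cell meshes and tracked sequences with known ground truth.

Everything downstream (tension inference, isogonal decomposition, T1
detection) is testable against meshes constructed so that the truth is
known exactly:

* a *tension triangulation* is laid out in the plane (edge lengths are the
  relative tensions),
* the cell array is its l0-scaled Voronoi dual (vertices at circumcenters)
  — the zero-isogonal-strain reference,
* an optional isogonal map and vertex noise are applied on top.

Time series embed a quartet-model trajectory in a hexagonal surround: the
six vertices of the central quartet move according to the simulated
angles/lengths while the rest of the lattice stays put, producing tracked
sequences with programmed (active or passive) neighbor exchanges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

from .geometry import DEFAULT_L0, ltc_statistics
from .mesh import CellMesh, MeshValidationError, TrackedSequence, mesh_from_cells
from .quartet import ModelParams, QuartetTrajectory, simulate_active, \
    simulate_passive

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "TensionTriangulation",
    "make_tension_triangulation",
    "realize_mesh_from_tensions",
    "generate_t1_sequence",
    "snail_like_and_wt_like_presets",
]

PATTERNS = ("uniform", "anisotropic", "alternating_bridge", "cable", "random")


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic generator.

    ``eps`` controls the pattern amplitude: for ``anisotropic`` the DV
    stretch of the triangulation, for ``alternating_bridge``/``cable`` the
    long/short-edge contrast (base 1+eps vs legs 1-eps and vice versa;
    eps < 1/3 keeps the triangle inequality).
    """

    nx: int = 12
    ny: int = 12
    pattern: str = "uniform"
    eps: float = 0.0
    isogonal: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    l0: float = DEFAULT_L0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth travelling with a synthetic mesh (sidecar, never
    recomputed): per-interface absolute and relative tensions keyed by the
    adjacent cell pair, the applied isogonal map, and programmed events."""

    edge_tension: dict = field(default_factory=dict)
    edge_rel_tension: dict = field(default_factory=dict)
    isogonal: np.ndarray | None = None
    events: list = field(default_factory=list)

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def tension(self, a: int, b: int) -> float:
        return self.edge_tension[self._key(a, b)]

    def rel_tension(self, a: int, b: int) -> float:
        return self.edge_rel_tension[self._key(a, b)]

    def to_json(self, path) -> None:
        doc = {
            "schema": "tigon-truth-1",
            "edge_tension": {f"{a},{b}": t for (a, b), t in
                             self.edge_tension.items()},
            "edge_rel_tension": {f"{a},{b}": t for (a, b), t in
                                 self.edge_rel_tension.items()},
            "isogonal": None if self.isogonal is None
            else np.asarray(self.isogonal).tolist(),
            "events": self.events,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        gt = cls()
        for k, v in doc["edge_tension"].items():
            a, b = (int(x) for x in k.split(","))
            gt.edge_tension[(a, b)] = v
        for k, v in doc["edge_rel_tension"].items():
            a, b = (int(x) for x in k.split(","))
            gt.edge_rel_tension[(a, b)] = v
        if doc["isogonal"] is not None:
            gt.isogonal = np.array(doc["isogonal"])
        gt.events = [tuple(e) if isinstance(e, list) else e
                     for e in doc["events"]]
        return gt


@dataclass
class TensionTriangulation:
    """Planar triangulation whose edge lengths are relative tensions."""

    points: np.ndarray
    triangles: np.ndarray

    def edge_set(self) -> set[tuple[int, int]]:
        out = set()
        for s in self.triangles:
            for a, b in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
                out.add((min(a, b), max(a, b)))
        return out

    def edge_length(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.points[a] - self.points[b]))

    def triangle_sides(self) -> np.ndarray:
        p = self.points
        s = self.triangles
        return np.stack(
            [
                np.linalg.norm(p[s[:, 0]] - p[s[:, 1]], axis=1),
                np.linalg.norm(p[s[:, 1]] - p[s[:, 2]], axis=1),
                np.linalg.norm(p[s[:, 2]] - p[s[:, 0]], axis=1),
            ],
            axis=1,
        )

    def interior_point_mask(self, margin: float | None = None) -> np.ndarray:
        """Points at least ``margin`` (default ~1.6 median edge lengths)
        from the bounding box."""
        if margin is None:
            margin = 1.6 * float(np.median(
                [self.edge_length(a, b) for a, b in self.edge_set()]
            ))
        extent = self.points.max(axis=0) - self.points.min(axis=0)
        m = np.minimum(margin, extent / 4.0)  # keep an interior on flat lattices
        lo = self.points.min(axis=0) + m
        hi = self.points.max(axis=0) - m
        return np.all((self.points >= lo) & (self.points <= hi), axis=1)

    def interior_triangle_sides(self, margin: float | None = None) -> np.ndarray:
        """Sides of triangles whose vertices all lie inside the margin."""
        mask = self.interior_point_mask(margin)
        keep = np.all(mask[self.triangles], axis=1)
        return self.triangle_sides()[keep]

    def ltc_statistics(self, margin: float | None = None,
                       bins: int = 20) -> dict:
        return ltc_statistics(self.interior_triangle_sides(margin), bins=bins)


def _lattice_points_triangles(nx: int, ny: int, w: float, h: float):
    idx = {}
    pts = []
    for j in range(ny):
        for i in range(nx):
            idx[(i, j)] = len(pts)
            pts.append(((i + 0.5 * (j % 2)) * w, j * h))
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a, b = idx[(i, j)], idx[(i + 1, j)]
            c, d = idx[(i, j + 1)], idx[(i + 1, j + 1)]
            if j % 2 == 0:
                tris.append((a, b, c))
                tris.append((b, d, c))
            else:
                tris.append((a, b, d))
                tris.append((a, d, c))
    return np.array(pts, dtype=float), np.array(tris, dtype=int)


def make_tension_triangulation(spec: GeneratorSpec) -> TensionTriangulation:
    """Lay out a tension triangulation in the plane.

    Lattice patterns are regular rows of isosceles triangles
    (``alternating_bridge``: long horizontal base 1+eps, short legs 1-eps,
    obtuse for eps > (sqrt(2)-1)/(sqrt(2)+1); ``cable``: the opposite,
    always acute); ``anisotropic`` stretches a unit triangular lattice by
    (1+eps) along DV; ``random`` is the Delaunay triangulation of jittered
    seed-reproducible uniform points.
    """
    eps = spec.eps
    if spec.pattern in ("alternating_bridge", "cable") and eps >= 1 / 3:
        raise ValueError(
            f"eps = {eps} >= 1/3 violates the triangle inequality for the "
            f"{spec.pattern} pattern"
        )
    if spec.pattern == "random":
        rng = np.random.default_rng(spec.seed)
        pts = rng.random((spec.nx * spec.ny, 2)) * [spec.nx, spec.ny]
        tri = Delaunay(pts)
        return TensionTriangulation(pts, np.asarray(tri.simplices))
    if spec.pattern in ("uniform", "anisotropic"):
        pts, tris = _lattice_points_triangles(
            spec.nx, spec.ny, 1.0, math.sqrt(3) / 2
        )
        if spec.pattern == "anisotropic":
            pts = pts @ np.diag([1.0, 1.0 + eps]).T
        return TensionTriangulation(pts, tris)
    if spec.pattern == "alternating_bridge":
        w, leg = 1.0 + eps, 1.0 - eps
    else:  # cable
        w, leg = 1.0 - eps, 1.0 + eps
    h2 = leg * leg - 0.25 * w * w
    if h2 <= 0:
        raise ValueError(
            f"pattern {spec.pattern} with eps = {eps}: rows degenerate"
        )
    pts, tris = _lattice_points_triangles(spec.nx, spec.ny, w, math.sqrt(h2))
    return TensionTriangulation(pts, tris)


def _circumcenter(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-14:
        raise MeshValidationError("degenerate triangle in triangulation")
    ux = (
        (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
    ) / d
    uy = (
        (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
    ) / d
    return np.array([ux, uy])


def realize_mesh_from_tensions(
    tri: TensionTriangulation,
    l0: float = DEFAULT_L0,
    isogonal: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    frame_time: float = 0.0,
) -> tuple[CellMesh, GroundTruth]:
    """Realize the Voronoi cell array of a tension triangulation.

    Cell vertices are placed at the l0-scaled circumcenters of the tension
    triangles, an optional linear isogonal map is applied, then optional
    Gaussian vertex noise (``noise_sigma`` as a fraction of the mean edge
    length).  One cell per interior triangulation point (points whose
    triangle fan is closed); the cell id is the point index.

    The triangulation must be Delaunay-valid (no adjacent triangle pair
    past the concyclic configuration), otherwise the Voronoi cell array
    would contain flipped edges and an error is raised.

    Returns the mesh and the exact :class:`GroundTruth`.
    """
    pts = tri.points
    # circumcenter per triangle
    centers = np.array(
        [_circumcenter(pts[a], pts[b], pts[c]) for a, b, c in tri.triangles]
    )
    # adjacency: edge -> incident triangles
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for k, s in enumerate(tri.triangles):
        for a, b in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
            edge_tris.setdefault((min(a, b), max(a, b)), []).append(k)
    # Delaunay validity: the signed circumcenter separation across every
    # interior edge (the Voronoi edge length) must be positive
    for (a, b), ts in edge_tris.items():
        if len(ts) != 2:
            continue
        e = pts[b] - pts[a]
        n = np.array([-e[1], e[0]])
        apex1 = next(int(x) for x in tri.triangles[ts[0]]
                     if x not in (a, b))
        w = 1.0 if float(n @ (pts[apex1] - pts[a])) > 0 else -1.0
        sep = w * float(n @ (centers[ts[0]] - centers[ts[1]]))
        if sep <= 1e-12:
            raise MeshValidationError(
                f"triangulation edge ({a},{b}) is at or past the concyclic "
                "configuration; Voronoi cell array would be flipped"
            )
    # triangle fans around each point
    point_tris: dict[int, list[int]] = {}
    for k, s in enumerate(tri.triangles):
        for p in s:
            point_tris.setdefault(int(p), []).append(k)
    edge_count: dict[tuple[int, int], int] = {e: len(ts) for e, ts in
                                              edge_tris.items()}

    def fan_closed(p: int) -> bool:
        for t in point_tris.get(p, []):
            s = tri.triangles[t]
            others = [int(x) for x in s if x != p]
            e = (min(p, others[0]), max(p, others[0]))
            f = (min(p, others[1]), max(p, others[1]))
            if edge_count[e] != 2 or edge_count[f] != 2:
                return False
        return len(point_tris.get(p, [])) >= 3

    rng = np.random.default_rng(seed)
    A = np.eye(2) if isogonal is None else np.asarray(isogonal, dtype=float)
    mean_edge = float(
        np.mean([tri.edge_length(a, b) for a, b in tri.edge_set()])
    ) * l0 / math.sqrt(3)

    interior_pts = [p for p in sorted(point_tris) if fan_closed(p)]
    if isogonal is None:
        positions = centers * l0
    else:
        positions = _isogonal_positions(
            tri, centers, edge_tris, point_tris, interior_pts, A, l0
        )
    noise = {}

    def vpos(t_idx: int) -> np.ndarray:
        if t_idx not in noise:
            base = positions[t_idx].copy()
            if noise_sigma > 0:
                base = base + noise_sigma * mean_edge * rng.standard_normal(2)
            noise[t_idx] = base
        return noise[t_idx]

    loops = {}
    for p in interior_pts:
        fans = point_tris[p]
        # order incident triangles CCW by circumcenter angle around point
        ang = [
            math.atan2(*(centers[t] - pts[p])[::-1]) for t in fans
        ]
        ordered = [t for _, t in sorted(zip(ang, fans))]
        loops[p] = [vpos(t) for t in ordered]

    mesh = mesh_from_cells(loops, frame_time=frame_time, tol=1e-9)

    gt = GroundTruth(isogonal=A.copy())
    for (a, b), ts in edge_tris.items():
        t = tri.edge_length(a, b)
        gt.edge_tension[(a, b)] = t
        if len(ts) == 2:
            flanks = []
            for k in ts:
                for u, v in ((tri.triangles[k][0], tri.triangles[k][1]),
                             (tri.triangles[k][1], tri.triangles[k][2]),
                             (tri.triangles[k][2], tri.triangles[k][0])):
                    key = (min(u, v), max(u, v))
                    if key != (a, b):
                        flanks.append(tri.edge_length(*key))
            gt.edge_rel_tension[(a, b)] = t / (sum(flanks) / 4.0)
    return mesh, gt


def _lattice_isogonal(
    tri: TensionTriangulation,
    centers: np.ndarray,
    edge_tris: dict,
    point_tris: dict,
    interior_pts: list[int],
    A: np.ndarray,
    l0: float,
) -> np.ndarray | None:
    """Exact isogonal deformation for lattice (3-direction-class) duals.

    On a Bravais-lattice triangulation the Voronoi edges fall into three
    direction classes and the isogonal family is a per-class rescaling of
    their lengths.  Vertex positions are linear in the three class
    lengths; fitting the (centrosymmetric, hence exact area-) centroids to
    ``A @ (l0 * generator)`` is a 5-unknown least-squares problem.
    Returns None when the dual is not a 3-class lattice or the map ``A``
    is incompatible (nonzero fit residual).
    """
    n_tri = len(tri.triangles)
    inter_edges = [(e, ts) for e, ts in edge_tris.items() if len(ts) == 2]
    cls_of: dict[tuple[int, int], int] = {}
    cls_dirs: list[float] = []
    for (a, b), ts in inter_edges:
        d = centers[ts[1]] - centers[ts[0]]
        ln = np.linalg.norm(d)
        if ln < 1e-12:
            return None
        ang = math.atan2(d[1], d[0]) % math.pi
        for k, ref in enumerate(cls_dirs):
            if min(abs(ang - ref), math.pi - abs(ang - ref)) < 1e-9:
                cls_of[(a, b)] = k
                break
        else:
            cls_dirs.append(ang)
            cls_of[(a, b)] = len(cls_dirs) - 1
        if len(cls_dirs) > 3:
            return None
    n_cls = len(cls_dirs)
    # coefficients: x_tau = B[tau] @ mu (+ translation), via BFS
    B = np.full((n_tri, 2, n_cls), np.nan)
    adj: dict[int, list[tuple[int, np.ndarray, int]]] = {}
    for (a, b), ts in inter_edges:
        d = centers[ts[1]] - centers[ts[0]]
        u = d / np.linalg.norm(d)
        k = cls_of[(a, b)]
        adj.setdefault(ts[0], []).append((ts[1], u, k))
        adj.setdefault(ts[1], []).append((ts[0], -u, k))
    from collections import deque

    B[0] = 0.0
    queue = deque([0])
    while queue:
        t0 = queue.popleft()
        for t1, u, k in adj.get(t0, []):
            step = np.zeros((2, n_cls))
            step[:, k] = u
            cand = B[t0] + step
            if np.isnan(B[t1]).any():
                B[t1] = cand
                queue.append(t1)
            elif np.abs(B[t1] - cand).max() > 1e-9:
                return None  # loop closure fails: not a coherent lattice
    if np.isnan(B).any():
        return None  # disconnected dual
    # fit class lengths + translation to the mapped generators
    rows, rhs = [], []
    for p in interior_pts:
        fan = point_tris[p]
        Bc = np.mean([B[t] for t in fan], axis=0)
        tgt = A @ (tri.points[p] * l0)
        rows.append(np.concatenate([Bc[0], [1.0, 0.0]]))
        rhs.append(tgt[0])
        rows.append(np.concatenate([Bc[1], [0.0, 1.0]]))
        rhs.append(tgt[1])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    mu, trans = sol[:n_cls], sol[n_cls:]
    resid = np.abs(np.array(rows) @ sol - np.array(rhs)).max()
    if resid > 1e-9 * l0 or np.any(mu <= 0):
        return None
    return np.einsum("tik,k->ti", B, mu) + trans


def _isogonal_positions(
    tri: TensionTriangulation,
    centers: np.ndarray,
    edge_tris: dict,
    point_tris: dict,
    interior_pts: list[int],
    A: np.ndarray,
    l0: float,
) -> np.ndarray:
    """Vertex positions of an exact isogonal deformation.

    Every Voronoi-edge direction is kept fixed (hard constraints, so all
    vertex angles are exactly preserved and tension inference is
    unaffected) while the cell centroids are fitted in least squares to
    the linear image ``A @ (l0 * generator)``.  On lattice patterns with a
    compatible (axis-aligned diagonal) map the fit is exact; otherwise the
    residual is the best angle-preserving approximation.
    """
    pts = tri.points
    n_tri = len(tri.triangles)
    crows = []
    for (a, b), ts in edge_tris.items():
        if len(ts) != 2:
            continue
        d = pts[b] - pts[a]  # Voronoi edge is perpendicular to this
        row = np.zeros(2 * n_tri)
        row[2 * ts[0]: 2 * ts[0] + 2] = d
        row[2 * ts[1]: 2 * ts[1] + 2] = -d
        crows.append(row)
    C = np.array(crows)
    wrows, y = [], []
    for p in interior_pts:
        fan = point_tris[p]
        row = np.zeros(2 * n_tri)
        for t in fan:
            row[2 * t] += 1.0 / len(fan)
        row2 = np.roll(row, 1)
        wrows += [row, row2]
        target = A @ (pts[p] * l0)
        y += [target[0], target[1]]
    W = np.array(wrows)
    y = np.array(y)

    out = _lattice_isogonal(tri, centers, edge_tris, point_tris,
                            interior_pts, A, l0)
    if out is None:
        # general triangulation: best angle-preserving vertex-average fit
        from scipy.linalg import null_space

        N = null_space(C)
        x_lin = ((centers * l0) @ A.T).ravel()
        lam = 1e-7
        M = np.vstack([W @ N, lam * N])
        rhs = np.concatenate([y, lam * x_lin])
        z, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        out = (N @ z).reshape(n_tri, 2)
    # guard against inverted (negative-length) Voronoi edges on the cells
    # that are actually emitted
    interior = set(interior_pts)
    for (a, b), ts in edge_tris.items():
        if len(ts) != 2 or not ({a, b} & interior):
            continue
        old = centers[ts[0]] - centers[ts[1]]
        new = out[ts[0]] - out[ts[1]]
        if float(old @ new) < 0:
            raise MeshValidationError(
                f"isogonal map inverts the interface dual to edge ({a},{b})"
            )
    return out


# --------------------------------------------------------------- honeycomb


def _honeycomb(nx: int, ny: int, l_c: float, l_s: float):
    """Hexagonal cell array with vertical edges l_c and slant edges l_s.

    Returns (cell centers dict, base vertex offsets, lattice vectors).
    Cells are keyed (i, j); vertices are returned per cell as CCW offset
    labels resolved through a shared corner-point table, so adjacent cells
    reference identical coordinates.
    """
    s = l_s * math.sqrt(3) / 2  # sin(60 deg)
    e = l_s / 2                 # cos(60 deg)
    h = l_c / 2
    a1 = np.array([2 * s, 0.0])
    a2 = np.array([s, l_c + e])
    offsets = [
        (-s, -h), (0.0, -h - e), (s, -h), (s, h), (0.0, h + e), (-s, h)
    ]
    centers = {
        (i, j): i * a1 + j * a2 for j in range(ny) for i in range(nx)
    }
    return centers, offsets, (a1, a2)


def _hex_cell_id(i: int, j: int, nx: int) -> int:
    return j * nx + i


def generate_t1_sequence(
    mode: str,
    nx: int = 9,
    ny: int = 9,
    params: ModelParams | None = None,
    quartets: list[tuple[int, int]] | None = None,
    frame_interval_min: float = 0.25,
    t_max: float | None = None,
    dl_iso_prestretch: float = 0.0,
    seed: int = 0,
    angle_sigma_deg: float = 4.0,
    n_events: int | None = None,
) -> tuple[TrackedSequence, GroundTruth]:
    """Tracked sequence embedding programmed T1 events in a hexagonal
    lattice.

    ``mode`` is 'active' (tension-feedback quartet dynamics), 'passive'
    (prescribed contraction at constant tension), 'mixed' (feedback plus a
    prescribed isogonal contraction of comparable magnitude) or 'none'
    (static lattice, no events).  Each programmed quartet is centred on the vertical edge
    left of lattice cell (i, j); quartets must be pairwise non-adjacent.
    ``dl_iso_prestretch`` stretches the vertical interfaces (and the model
    target shape) by a constant isogonal length in um.

    The six vertices of each quartet follow the simulated angles and
    lengths exactly, so tension inference at the central vertices recovers
    the model tensions; the surround stays at its resting geometry.
    """
    if mode not in ("active", "passive", "mixed", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or ModelParams()
    l_h = params.l_rest
    dl = dl_iso_prestretch
    if dl != 0.0:
        s0 = params.s0.copy()
        s0[1, 1] += dl
        params = replace(params, s0=s0)
        params.__post_init__()
    if quartets is None:
        if mode == "none":
            quartets = []
        elif n_events is None or n_events == 1:
            quartets = [(nx // 2, ny // 2)]
        else:
            quartets = _spread_quartets(nx, ny, n_events)
    _check_quartets(quartets, nx, ny)

    centers, offsets, _ = _honeycomb(nx, ny, l_h + dl, l_h)

    # base corner points, shared between cells through quantized keys
    def key_of(p: np.ndarray) -> tuple[int, int]:
        return (round(p[0] * 1e7), round(p[1] * 1e7))

    base_pos: dict[tuple[int, int], np.ndarray] = {}
    cell_keys: dict[int, list[tuple[int, int]]] = {}
    for (i, j), c in centers.items():
        ks = []
        for ox, oy in offsets:
            p = c + np.array([ox, oy])
            k = key_of(p)
            base_pos.setdefault(k, p)
            ks.append(k)
        cell_keys[_hex_cell_id(i, j, nx)] = ks

    # simulate one trajectory per quartet
    rng = np.random.default_rng(seed)
    trajs: list[QuartetTrajectory] = []
    horizon = t_max
    for _ in quartets:
        if mode in ("active", "mixed"):
            ang = np.radians(120.0 + angle_sigma_deg * rng.standard_normal(3))
            ang *= 2 * math.pi / ang.sum()
            t = np.sin(np.roll(ang, -1))
            t = np.sort(t / t.mean())[::-1]
            rate = -l_h / 24.0 if mode == "mixed" else 0.0
            traj = simulate_active(t, params, t_max=horizon or 40.0,
                                   hold_dl_iso=dl if mode == "mixed" else None,
                                   dl_iso_rate=rate,
                                   record_every=1, post_flip_window=6.0)
        else:
            rate = (l_h / 12.0) * (1 + 0.05 * rng.standard_normal())
            traj = simulate_passive(params, rate=rate,
                                    t_max=horizon or 30.0, record_every=1)
        trajs.append(traj)
    if t_max is None:
        flips = [tr.flip_time for tr in trajs if tr.flip_time is not None]
        t_max = (max(flips) + 5.0) if flips else 5.0

    gt = GroundTruth()
    quartet_info = []
    base_lengths = np.array([l_h + dl, l_h, l_h])
    base_phis = np.radians([120.0, 120.0, 120.0])
    for (i0, j0), traj in zip(quartets, trajs):
        L = _hex_cell_id(i0 - 1, j0, nx)
        R = _hex_cell_id(i0, j0, nx)
        T = _hex_cell_id(i0 - 1, j0 + 1, nx)
        B = _hex_cell_id(i0, j0 - 1, nx)
        m_e = centers[(i0, j0)] + np.array([-l_h * math.sqrt(3) / 2, 0.0])
        base_positions = _quartet_positions(m_e, base_lengths, base_phis)
        info = {
            "cells": (L, R, T, B),
            "m_e": m_e,
            "traj": traj,
            "keys": {name: key_of(p) for name, p in base_positions.items()},
            "p_key": ("new", i0, j0, "p"),
            "q_key": ("new", i0, j0, "q"),
            "frozen": None,
        }
        quartet_info.append(info)
        if traj.flip_time is not None and traj.flip_time <= t_max:
            gt.events.append((L, R, T, B, float(traj.flip_time)))

    n_frames = int(math.floor(t_max / frame_interval_min)) + 1
    frames = []
    for fidx in range(n_frames):
        tt = fidx * frame_interval_min
        pos = dict(base_pos)
        loops = {cid: list(ks) for cid, ks in cell_keys.items()}
        for info in quartet_info:
            _apply_quartet(info, tt, pos, loops, nx)
        coord_loops = {
            cid: [pos[k] for k in ks] for cid, ks in loops.items()
        }
        frames.append(mesh_from_cells(coord_loops, frame_time=tt, tol=1e-6))
    return TrackedSequence(frames), gt


def _state_at(traj: QuartetTrajectory, t: float):
    times = traj.times
    idx = int(np.searchsorted(times, t, side="right")) - 1
    idx = max(0, min(idx, len(times) - 1))
    # prefer consistent topology at the exact flip frame
    return traj.states[idx]


def _dir(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _quartet_positions(
    m_e: np.ndarray, lengths: np.ndarray, phis: np.ndarray
) -> dict[str, np.ndarray]:
    """Positions of all 16 vertices of the four quartet hexagons, pre-flip.

    The central (class-0) interface is vertical with midpoint ``m_e``;
    ``lengths`` and ``phis`` are the model's per-class interface lengths
    and vertex angles.  Every vertex of the cells L, R, T, B follows the
    periodic-model geometry, so tension inference anywhere on the kite
    reproduces the model tensions exactly.
    """
    l0, l1, l2 = lengths
    u = m_e + np.array([0.0, l0 / 2])
    v = m_e - np.array([0.0, l0 / 2])
    # fan at u: central edge points down (270 deg); counter-clockwise the
    # class-1 flank follows after phi_2, then the class-2 flank after phi_0
    a1 = math.radians(270) + phis[2]
    a2 = a1 + phis[0]
    b1 = math.radians(90) + phis[2]
    b2 = b1 + phis[0]
    w_ur = u + l1 * _dir(a1)
    w_ul = u + l2 * _dir(a2)
    w_ll = v + l1 * _dir(b1)
    w_lr = v + l2 * _dir(b2)
    up = np.array([0.0, l0])
    pos = {
        "u": u, "v": v,
        "w_ur": w_ur, "w_ul": w_ul, "w_ll": w_ll, "w_lr": w_lr,
        # right cell's outer corners (centrosymmetric hexagon closure)
        "c_rlr": w_lr + l1 * _dir(a1),
        "c_rur": w_ur - l2 * _dir(a2),
        # left cell
        "c_lul": w_ul + l1 * _dir(b1),
        "c_lll": w_ul + l1 * _dir(b1) - up,
        # top cell
        "c_tr": w_ur + up,
        "c_tt": w_ur + up + l2 * _dir(a2),
        "c_tl": w_ul + up,
        # bottom cell
        "c_bl": w_ll - up,
        "c_bb": w_ll - up + l2 * _dir(b2),
        "c_br": w_lr - up,
    }
    return pos


def _apply_quartet(info, t: float, pos, loops, nx: int) -> None:
    traj: QuartetTrajectory = info["traj"]
    st = _state_at(traj, t)
    keys = info["keys"]
    m_e = info["m_e"]
    L, R, T, B = info["cells"]
    phis = st.phis
    l = st.lengths
    if st.topology == "pre":
        for name, p in _quartet_positions(m_e, l, phis).items():
            pos[keys[name]] = p
    else:
        # freeze the outer quartet corners at their last pre-flip position
        if info["frozen"] is None:
            last_pre = traj.pre_flip()[-1]
            info["frozen"] = _quartet_positions(
                m_e, last_pre.lengths, last_pre.phis
            )
        for name, pnt in info["frozen"].items():
            if name not in ("u", "v"):
                pos[keys[name]] = pnt
        p = m_e + np.array([-l[0] / 2, 0.0])
        q = m_e + np.array([l[0] / 2, 0.0])
        pk, qk = info["p_key"], info["q_key"]
        pos[pk] = p
        pos[qk] = q
        # fan at p: new central edge points right (0 deg)
        a1 = phis[2]
        a2 = a1 + phis[0]
        b1 = math.radians(180) + phis[2]
        b2 = b1 + phis[0]
        pos[keys["w_ul"]] = p + l[1] * _dir(a1)
        pos[keys["w_ll"]] = p + l[2] * _dir(a2)
        pos[keys["w_lr"]] = q + l[1] * _dir(b1)
        pos[keys["w_ur"]] = q + l[2] * _dir(b2)
        uk, vk = keys["u"], keys["v"]
        loops[L] = _replace_run(loops[L], [vk, uk], [pk])
        loops[R] = _replace_run(loops[R], [uk, vk], [qk])
        loops[T] = _replace_run(loops[T], [uk], [pk, qk])
        loops[B] = _replace_run(loops[B], [vk], [qk, pk])


def _replace_run(loop: list, old: list, new: list) -> list:
    n = len(loop)
    for i in range(n):
        if all(loop[(i + k) % n] == old[k] for k in range(len(old))):
            out = []
            skip = {(i + k) % n for k in range(len(old))}
            for j in range(n):
                if j == i:
                    out.extend(new)
                elif j not in skip:
                    out.append(loop[j])
            return out
    raise MeshValidationError("quartet loop bookkeeping failed")


def _check_quartets(quartets, nx: int, ny: int) -> None:
    seen: list[set[tuple[int, int]]] = []
    for (i, j) in quartets:
        if not (2 <= i <= nx - 3 and 2 <= j <= ny - 3):
            raise ValueError(
                f"quartet ({i},{j}) too close to the lattice boundary"
            )
        cells = {(i - 1, j), (i, j), (i - 1, j + 1), (i, j - 1)}
        grown = set()
        for (a, b) in cells:
            grown |= {
                (a, b), (a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1),
                (a - 1, b + 1), (a + 1, b - 1),
            }
        for other in seen:
            if grown & other:
                raise ValueError(
                    f"programmed quartets are adjacent near ({i},{j})"
                )
        seen.append(cells)


def _spread_quartets(nx: int, ny: int, n: int) -> list[tuple[int, int]]:
    out = []
    for j in range(2, ny - 2, 3):
        for i in range(2, nx - 2, 3):
            out.append((i, j))
            if len(out) == n:
                return out
    raise ValueError(f"lattice {nx}x{ny} too small for {n} quartets")


def passive_collapse_quartet(
    central_fraction: float, l0: float = DEFAULT_L0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Explicit symmetric passive-collapse construction.

    A hexagonal-reference cell quartet whose central interface is shrunk
    to ``central_fraction`` of its resting length by a pure isogonal
    deformation (all vertex angles stay at 120 degrees, tensions stay 1,
    slant edges keep their resting length).  Returns the five
    ``(tension vector, centroid difference)`` kite-edge pairs consumed by
    :func:`tigon.isogonal.quartet_isogonal`.

    At ``central_fraction = 1`` the quartet is the resting reference
    (identity tensor); at 0 (the neighbor exchange) the accumulated
    isogonal tensor is diag(1, 1/3) up to scale, aspect ratio sqrt(3).
    """
    l_h = l0 / math.sqrt(3)
    l_c = central_fraction * l_h
    r3 = math.sqrt(3)
    cents = {
        "L": np.array([-r3 * l_h / 2, 0.0]),
        "R": np.array([r3 * l_h / 2, 0.0]),
        "T": np.array([0.0, l_c + 0.5 * l_h]),
        "B": np.array([0.0, -(l_c + 0.5 * l_h)]),
    }
    nodes = {
        "L": np.array([-0.5, 0.0]),
        "R": np.array([0.5, 0.0]),
        "T": np.array([0.0, r3 / 2]),
        "B": np.array([0.0, -r3 / 2]),
    }
    pairs = [("L", "R"), ("L", "T"), ("R", "T"), ("L", "B"), ("R", "B")]
    return [(nodes[a] - nodes[b], cents[a] - cents[b]) for a, b in pairs]


def snail_like_and_wt_like_presets() -> tuple[dict, dict]:
    """Generator presets for the two study conditions.

    Both run active tension-feedback T1s; the *wt-like* preset applies a
    DV isogonal pre-stretch of 1.9 um (so neighbor exchanges occur above
    the sqrt(2) threshold) while the *snail-like* preset applies none (no
    ventral-furrow pull; collapse at the bare threshold).
    """
    common = dict(mode="active", nx=9, ny=9, frame_interval_min=0.25)
    snail = dict(common, dl_iso_prestretch=0.0)
    wt = dict(common, dl_iso_prestretch=1.9)
    return snail, wt
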