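"""Tension-isogonal decomposition.

Cortical force balance pins the *angles* of the cell array but leaves an
angle-preserving (isogonal) family of deformations unconstrained.  The
isogonal mode is quantified by the linear map ``I`` carrying the
tension-derived reference geometry into the observed centroidal geometry:

    l0 * I . T_ij = c_i - c_j

where ``T_ij`` are tension vectors of the triangulation (already
perpendicular to the interfaces), ``c_i`` cell centroids and ``l0`` the
tension-to-length scale.  At a single vertex the map is determined exactly
by the tension triangle and the triangle of the three adjacent centroids;
for a cell quartet the five kite edges overdetermine it and ``I`` is the
least-squares fit.  ``I = identity`` iff the observed array is the
l0-scaled Voronoi reference of its tension triangulation.

On the interface level the same decomposition splits each length into
``l = l_ref + dl_iso`` with the Voronoi reference length ``l_ref``
determined purely by local tensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import polar

from .geometry import DEFAULT_L0, voronoi_reference_length
from .inference import kite_of_edge, vertex_tension_nodes
from .mesh import CellMesh

__all__ = [
    "IsogonalTensor",
    "vertex_isogonal",
    "vertex_isogonal_table",
    "quartet_isogonal",
    "quartet_tension_edges",
    "quartet_shape_aspect",
    "edge_length_decomposition",
    "grid_average_isogonal",
    "calibrate_l0",
]


@dataclass
class IsogonalTensor:
    """2x2 isogonal deformation tensor with its reference scale.

    ``aspect_ratio`` is sqrt(sigma_max / sigma_min) of the singular values
    — the convention under which the symmetric passive-collapse
    construction (120-degree angles kept, central edge shrunk to zero from
    the hexagonal reference) reads sqrt(3).
    """

    matrix: np.ndarray
    l0: float = DEFAULT_L0
    residual: float = 0.0
    association: int | tuple | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))

    def polar_parts(self) -> tuple[np.ndarray, np.ndarray]:
        """(rotation, symmetric stretch) with matrix = rotation @ stretch."""
        r, s = polar(self.matrix, side="right")
        return r, s

    @property
    def stretch(self) -> np.ndarray:
        return self.polar_parts()[1]

    @property
    def singular_values(self) -> np.ndarray:
        return np.linalg.svd(self.matrix, compute_uv=False)

    @property
    def unimodular(self) -> np.ndarray:
        """Determinant-normalized matrix: the shape of the deformation with
        the overall scale (set by the local tension normalization) divided
        out."""
        d = self.det
        if d <= 0:
            raise ValueError("isogonal tensor has non-positive determinant")
        return self.matrix / math.sqrt(d)

    @property
    def aspect_ratio(self) -> float:
        s = self.singular_values
        if s[1] <= 0:
            return float("inf")
        return float(math.sqrt(s[0] / s[1]))


def vertex_isogonal(
    tension_triangle_points: np.ndarray,
    centroid_triangle_points: np.ndarray,
    l0: float = DEFAULT_L0,
) -> IsogonalTensor:
    """Exact isogonal tensor at a vertex.

    Parameters
    ----------
    tension_triangle_points
        (3, 2) tension-triangulation node positions of the three adjacent
        cells, already rotated into physical orientation (see
        :func:`tigon.inference.vertex_tension_nodes`); row k must
        correspond to the same cell as row k of the centroid triangle.
    centroid_triangle_points
        (3, 2) centroids of the same three cells, in the same order.

    The unique linear map with ``I @ (l0 * tension edge) = centroid edge``
    for the two independent edges (translations discarded).
    """
    t = np.asarray(tension_triangle_points, dtype=float)
    c = np.asarray(centroid_triangle_points, dtype=float)
    M = np.column_stack([t[1] - t[0], t[2] - t[0]]) * l0
    C = np.column_stack([c[1] - c[0], c[2] - c[0]])
    if abs(np.linalg.det(M)) < 1e-14 * (np.abs(M).max() or 1.0) ** 2:
        raise ValueError("degenerate tension triangle")
    return IsogonalTensor(C @ np.linalg.inv(M), l0=l0)


def vertex_isogonal_table(
    mesh: CellMesh, l0: float = DEFAULT_L0, frame: int = 0
) -> pd.DataFrame:
    """Per-vertex isogonal tensors over a frame.

    Columns: frame, vertex_id, x, y, Ixx, Ixy, Iyx, Iyy, residual.
    Interior degree-3 vertices only; the tension triangle is built from
    inferred tensions at the vertex and matched to the adjacent cell
    centroids by shared cell identity.
    """
    rows = []
    for vid in mesh.interior_vertices(degree=3):
        cells, nodes = vertex_tension_nodes(mesh, vid)
        cents = np.array([mesh.cell_centroid(c) for c in cells])
        tensor = vertex_isogonal(nodes, cents, l0=l0)
        p = mesh.position(vid)
        I = tensor.matrix
        rows.append(
            {
                "frame": frame,
                "vertex_id": vid,
                "x": p[0],
                "y": p[1],
                "Ixx": I[0, 0],
                "Ixy": I[0, 1],
                "Iyx": I[1, 0],
                "Iyy": I[1, 1],
                "residual": 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["frame", "vertex_id", "x", "y", "Ixx", "Ixy", "Iyx", "Iyy",
                 "residual"],
    )


def quartet_isogonal(
    edges: list[tuple[np.ndarray, np.ndarray]],
    l0: float = DEFAULT_L0,
) -> IsogonalTensor:
    """Least-squares isogonal tensor of a cell quartet.

    Parameters
    ----------
    edges
        List of ``(tension_vector, centroid_difference)`` pairs, one per
        kite edge (five for a full quartet, at least three independent
        ones required).  Minimizes ``sum || l0 * I @ T - dc ||^2`` over
        2x2 matrices; all edges weighted equally.
    """
    if len(edges) < 2:
        raise ValueError("at least two edge correspondences required")
    A = np.zeros((2 * len(edges), 4))
    b = np.zeros(2 * len(edges))
    for k, (tv, dc) in enumerate(edges):
        tv = np.asarray(tv, dtype=float) * l0
        dc = np.asarray(dc, dtype=float)
        A[2 * k, 0:2] = tv
        A[2 * k + 1, 2:4] = tv
        b[2 * k] = dc[0]
        b[2 * k + 1] = dc[1]
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("rank-deficient quartet system")
    resid = float(np.linalg.norm(A @ sol - b))
    return IsogonalTensor(sol.reshape(2, 2), l0=l0, residual=resid)


def quartet_tension_edges(
    mesh: CellMesh, interface_id: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(tension vector, centroid difference) pairs for the 5 kite edges.

    Tension vectors come from the two end-vertex tension triangles (scales
    matched on the shared side, mean flank tension normalized to 1); the
    two estimates of the shared edge are averaged.
    """
    q = mesh.quartet_of_edge(interface_id)
    u, v = q.end_vertices
    ca, cb = mesh.interfaces[interface_id].cell_pair
    cells_u, nodes_u = vertex_tension_nodes(mesh, u)
    cells_v, nodes_v = vertex_tension_nodes(mesh, v)
    nu = dict(zip(cells_u, nodes_u))
    nv = dict(zip(cells_v, nodes_v))
    # match the scale of the two triangles on the shared side
    su = np.linalg.norm(nu[ca] - nu[cb])
    sv = np.linalg.norm(nv[ca] - nv[cb])
    scale_v = su / sv
    # kite gauge: mean of the four flank tensions = 1
    apex_u = (set(cells_u) - {ca, cb}).pop()
    apex_v = (set(cells_v) - {ca, cb}).pop()
    flank = (
        np.linalg.norm(nu[ca] - nu[apex_u])
        + np.linalg.norm(nu[cb] - nu[apex_u])
        + scale_v * (np.linalg.norm(nv[ca] - nv[apex_v])
                     + np.linalg.norm(nv[cb] - nv[apex_v]))
    ) / 4.0
    g_u, g_v = 1.0 / flank, scale_v / flank
    cent = {c: mesh.cell_centroid(c) for c in (ca, cb, apex_u, apex_v)}
    edges = []
    shared_u = (nu[ca] - nu[cb]) * g_u
    shared_v = (nv[ca] - nv[cb]) * g_v
    edges.append((0.5 * (shared_u + shared_v), cent[ca] - cent[cb]))
    for c1, c2 in ((ca, apex_u), (cb, apex_u)):
        edges.append(((nu[c1] - nu[c2]) * g_u, cent[c1] - cent[c2]))
    for c1, c2 in ((ca, apex_v), (cb, apex_v)):
        edges.append(((nv[c1] - nv[c2]) * g_v, cent[c1] - cent[c2]))
    return edges


def quartet_isogonal_of_edge(
    mesh: CellMesh, interface_id: int, l0: float = DEFAULT_L0
) -> IsogonalTensor:
    """Least-squares isogonal tensor of the quartet around an interface."""
    tensor = quartet_isogonal(quartet_tension_edges(mesh, interface_id), l0=l0)
    tensor.association = interface_id
    return tensor


def quartet_shape_aspect(points: np.ndarray) -> float:
    """Aspect ratio of a point configuration.

    sqrt(lambda_max / lambda_min) of the second-moment (covariance) tensor
    of the points, so the ratio is in length units: stretching a point set
    by 2 along one axis doubles its aspect ratio.  Collinear input returns
    inf.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("at least three points required")
    g = np.cov(pts.T, bias=True)
    lam = np.sort(np.linalg.eigvalsh(g))
    if lam[0] <= 1e-15 * max(lam[1], 1.0):
        return float("inf")
    return float(math.sqrt(lam[1] / lam[0]))


def edge_length_decomposition(
    mesh: CellMesh, interface_id: int, l0: float = DEFAULT_L0
) -> tuple[float, float]:
    """Split an interface length into ``(l_ref, dl_iso)`` with
    ``l = l_ref + dl_iso``.

    ``l_ref`` is the signed Voronoi reference length of the inferred
    tension kite; ``dl_iso`` the isogonal remainder.  At the moment of a
    neighbor exchange (l = 0) the isogonal length equals ``-l_ref``.
    """
    kite = kite_of_edge(mesh, interface_id)
    l_ref = voronoi_reference_length(kite, l0=l0)
    l_obs = mesh.interface_length(interface_id)
    return float(l_ref), float(l_obs - l_ref)


def grid_average_isogonal(
    table: pd.DataFrame, spacing: float = 20.0,
    origin: tuple[float, float] | None = None,
    dv_axis: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Average per-vertex isogonal tensors on a square grid.

    Tensors are averaged component-wise (count-weighted) per grid cell and
    the mean is polar-decomposed; columns s1 >= s2 are the principal
    stretches, theta_deg the s1 axis, and dvdv the DV-DV component of the
    symmetric stretch along the fixed embryo axis ``dv_axis`` (+y by
    default).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if origin is None:
        origin = (table["x"].min(), table["y"].min())
    df = table.copy()
    df["gx"] = np.floor((df["x"] - origin[0]) / spacing).astype(int)
    df["gy"] = np.floor((df["y"] - origin[1]) / spacing).astype(int)
    ev = np.asarray(dv_axis, dtype=float)
    ev = ev / np.linalg.norm(ev)
    rows = []
    for (gx, gy), grp in df.groupby(["gx", "gy"]):
        I = np.array(
            [
                [grp["Ixx"].mean(), grp["Ixy"].mean()],
                [grp["Iyx"].mean(), grp["Iyy"].mean()],
            ]
        )
        _, s = polar(I, side="right")
        lam, vec = np.linalg.eigh(s)
        s1, s2 = float(lam[1]), float(lam[0])
        theta = math.atan2(vec[1, 1], vec[0, 1]) % math.pi
        rows.append(
            {
                "gx": gx,
                "gy": gy,
                "s1": s1,
                "s2": s2,
                "theta_deg": math.degrees(theta),
                "dvdv": float(ev @ s @ ev),
                "count": len(grp),
            }
        )
    return pd.DataFrame(
        rows, columns=["gx", "gy", "s1", "s2", "theta_deg", "dvdv", "count"]
    )


def calibrate_l0(mesh: CellMesh) -> float:
    """Estimate the tension-to-length scale from a frame.

    tigon's convention: the ratio of the mean observed interior interface
    length to the mean dimensionless Voronoi reference length of the
    inferred tension kites (computed at unit scale).  On a uniform
    hexagonal lattice this reduces to ``sqrt(3) * mean edge length``.
    """
    obs, ref = [], []
    for eid, itf in mesh.interfaces.items():
        if itf.is_boundary:
            continue
        try:
            kite = kite_of_edge(mesh, eid)
            r = voronoi_reference_length(kite, l0=1.0)
        except Exception:
            continue
        if r > 0:
            obs.append(mesh.interface_length(eid))
            ref.append(r)
    if not ref:
        raise ValueError("no valid interior kites for calibration")
    return float(np.mean(obs) / np.mean(ref))
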