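"""Relative cortical tension inference from vertex angles.

Force balance at a tri-cellular vertex makes the three tension vectors
close into a triangle whose internal angles are complementary to the
vertex angles; by the law of sines the tension on interface *i* is
proportional to the sine of the vertex angle between the *other two*
interfaces.  This fixes tensions at a vertex up to scale.

Per-interface *relative* tension combines the two end-vertex triangles
(the tension kite): the shared side is matched between the two triangles,
and the central tension is reported relative to the arithmetic mean of the
four flanking tensions (normalized to 1), the convention under which a
uniform hexagonal lattice reads exactly 1 and the square threshold
configuration reads sqrt(2).

The nematic tension anisotropy at a vertex is the traceless part of the
tension-weighted second-moment tensor of the unit interface directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import TensionKite
from .mesh import CellMesh, MeshValidationError

__all__ = [
    "InferenceUndefinedError",
    "VertexTensions",
    "EdgeRelativeTension",
    "infer_vertex_tensions",
    "infer_edge_tension",
    "infer_all_tensions",
    "kite_of_edge",
    "vertex_anisotropy",
    "grid_average_anisotropy",
    "vertex_tension_nodes",
]


class InferenceUndefinedError(ValueError):
    """No valid tension triangle exists for the given vertex angles."""


@dataclass(frozen=True)
class VertexTensions:
    """Relative tensions at a tri-cellular vertex, normalized to mean 1.

    ``tensions[i]`` belongs to ``edge_ids[i]``; the edges are in
    counter-clockwise order and ``angles[i]`` is the vertex angle from edge
    i to edge i+1.
    """

    vertex_id: int
    edge_ids: tuple[int, int, int]
    tensions: tuple[float, float, float]
    angles: tuple[float, float, float]


@dataclass(frozen=True)
class EdgeRelativeTension:
    """Central-interface tension with the mean of the 4 flanking tensions
    normalized to 1; ``consistency`` is the relative disagreement of the
    two one-triangle estimates (0 on integrable meshes)."""

    interface_id: int
    t_rel: float
    consistency: float


def infer_vertex_tensions(angles: np.ndarray) -> np.ndarray:
    """Relative tensions from three vertex angles summing to 2*pi.

    ``angles[i]`` is the angle between (cyclically adjacent) interfaces i
    and i+1; the returned ``tensions[i]`` belongs to interface i and is
    proportional to ``sin(angles[(i + 1) % 3])`` (the angle between the
    other two interfaces), normalized to mean 1.

    Raises
    ------
    InferenceUndefinedError
        If any angle lies outside (0, pi): the complementary tension
        triangle would not close.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (3,):
        raise InferenceUndefinedError("exactly three vertex angles required")
    if abs(float(angles.sum()) - 2 * math.pi) > 1e-6:
        raise InferenceUndefinedError(
            f"vertex angles sum to {angles.sum()}, expected 2*pi"
        )
    if np.any(angles <= 0) or np.any(angles >= math.pi):
        raise InferenceUndefinedError(
            f"vertex angle outside (0, 180 deg): {np.degrees(angles)}"
        )
    t = np.sin(np.roll(angles, -1))
    return t / t.mean()


def _vertex_triangle(mesh: CellMesh, vertex_id: int):
    """Sorted edges, angles and law-of-sines tensions (mean 1) at a vertex."""
    angles, eids = mesh.vertex_angles(vertex_id)
    if len(eids) != 3:
        raise InferenceUndefinedError(
            f"vertex {vertex_id} has degree {len(eids)} != 3 "
            "(fourfold configurations are skipped)"
        )
    t = infer_vertex_tensions(angles)
    return eids, angles, t


def vertex_tensions(mesh: CellMesh, vertex_id: int) -> VertexTensions:
    eids, angles, t = _vertex_triangle(mesh, vertex_id)
    return VertexTensions(
        vertex_id, tuple(eids), tuple(float(x) for x in t),
        tuple(float(a) for a in angles),
    )


def _end_ratio(mesh: CellMesh, vertex_id: int, central_edge: int):
    """(central : mean flank) ratio and per-side tensions at one end vertex."""
    eids, _, t = _vertex_triangle(mesh, vertex_id)
    i = eids.index(central_edge)
    tc = t[i]
    fl = [t[j] for j in range(3) if j != i]
    fl_edges = [eids[j] for j in range(3) if j != i]
    return tc / (0.5 * (fl[0] + fl[1])), tc, dict(zip(fl_edges, fl))


def infer_edge_tension(mesh: CellMesh, interface_id: int) -> EdgeRelativeTension:
    """Relative tension of one interface from its kite neighbourhood.

    Each end vertex yields a (central : mean-flank) ratio by the law of
    sines; the two triangles are combined by matching the shared side, so
    the reported value equals ``T_central / mean(four flank tensions)``.
    On noise-free force-balanced meshes the two one-triangle estimates
    agree exactly and ``consistency`` is 0.
    """
    q = mesh.quartet_of_edge(interface_id)
    u, v = q.end_vertices
    r_u, _, _ = _end_ratio(mesh, u, interface_id)
    r_v, _, _ = _end_ratio(mesh, v, interface_id)
    t_rel = 2.0 / (1.0 / r_u + 1.0 / r_v)  # shared-side matching
    consistency = abs(r_u - r_v) / (0.5 * (r_u + r_v))
    return EdgeRelativeTension(interface_id, float(t_rel), float(consistency))


def kite_of_edge(mesh: CellMesh, interface_id: int) -> TensionKite:
    """Tension kite of an interface, normalized to mean flank tension 1."""
    q = mesh.quartet_of_edge(interface_id)
    u, v = q.end_vertices
    r_u, tc_u, fl_u = _end_ratio(mesh, u, interface_id)
    r_v, tc_v, fl_v = _end_ratio(mesh, v, interface_id)
    shared = 2.0 / (1.0 / r_u + 1.0 / r_v)
    left = tuple(shared * fl_u[e] / tc_u for e in sorted(fl_u))
    right = tuple(shared * fl_v[e] / tc_v for e in sorted(fl_v))
    return TensionKite(shared=float(shared), left=left, right=right,
                       edge_id=interface_id)


def infer_all_tensions(
    mesh: CellMesh, frame: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Tension inference over a whole frame.

    Returns
    -------
    edges : DataFrame
        One row per interior interface with valid degree-3 end vertices:
        frame, edge_id, cell_a, cell_b, T_rel, consistency.
    vertices : DataFrame
        One row per interior degree-3 vertex: frame, vertex_id, e0..e2
        (counter-clockwise edge ids), T0..T2 (mean-1 tensions).
    skipped : list of dict
        Every skipped entity with a reason code (no silent skips).
    """
    skipped: list[dict] = []
    vrows = []
    for vid in mesh.vertices:
        if mesh.is_boundary_vertex(vid) or mesh.vertex_degree(vid) < 3:
            continue
        if mesh.vertex_degree(vid) != 3:
            skipped.append(
                {"kind": "vertex", "id": vid, "reason": "fourfold"}
            )
            continue
        try:
            vt = vertex_tensions(mesh, vid)
        except InferenceUndefinedError as e:
            skipped.append({"kind": "vertex", "id": vid, "reason": str(e)})
            continue
        vrows.append(
            {
                "frame": frame,
                "vertex_id": vid,
                "e0": vt.edge_ids[0],
                "e1": vt.edge_ids[1],
                "e2": vt.edge_ids[2],
                "T0": vt.tensions[0],
                "T1": vt.tensions[1],
                "T2": vt.tensions[2],
            }
        )
    erows = []
    for eid, itf in mesh.interfaces.items():
        if itf.is_boundary:
            continue
        try:
            est = infer_edge_tension(mesh, eid)
        except (MeshValidationError, InferenceUndefinedError) as e:
            skipped.append({"kind": "edge", "id": eid, "reason": str(e)})
            continue
        erows.append(
            {
                "frame": frame,
                "edge_id": eid,
                "cell_a": itf.cell_pair[0],
                "cell_b": itf.cell_pair[1],
                "T_rel": est.t_rel,
                "consistency": est.consistency,
            }
        )
    ecols = ["frame", "edge_id", "cell_a", "cell_b", "T_rel", "consistency"]
    vcols = ["frame", "vertex_id", "e0", "e1", "e2", "T0", "T1", "T2"]
    return (
        pd.DataFrame(erows, columns=ecols),
        pd.DataFrame(vrows, columns=vcols),
        skipped,
    )


def vertex_anisotropy(
    tensions: np.ndarray, directions: np.ndarray
) -> tuple[float, float]:
    """Nematic tension anisotropy (m, theta) at a vertex.

    ``sigma = sum_i T_i e_i (x) e_i`` over the unit interface directions;
    the anisotropy magnitude is the (absolute) eigenvalue of the traceless
    part Q and theta (in [0, pi)) the orientation of its positive
    eigenvector.  m is 0 for an isotropic configuration and scales linearly
    with the tensions.
    """
    t = np.asarray(tensions, dtype=float)
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    sigma = np.einsum("i,ij,ik->jk", t, d, d)
    q = sigma - 0.5 * np.trace(sigma) * np.eye(2)
    m = math.hypot(q[0, 0], q[0, 1])
    if m == 0.0:
        return 0.0, float("nan")
    theta = 0.5 * math.atan2(2 * q[0, 1], q[0, 0] - q[1, 1]) % math.pi
    return float(m), float(theta)


def vertex_anisotropy_table(mesh: CellMesh, frame: int = 0) -> pd.DataFrame:
    """Per-vertex anisotropy table: frame, vertex_id, x, y, m, theta."""
    rows = []
    for vid in mesh.interior_vertices(degree=3):
        angles, eids = mesh.vertex_angles(vid)
        t = infer_vertex_tensions(angles)
        p0 = mesh.position(vid)
        dirs = []
        for eid in eids:
            u, v = mesh.interfaces[eid].vertex_pair
            other = v if u == vid else u
            dirs.append(mesh.position(other) - p0)
        m, theta = vertex_anisotropy(t, np.array(dirs))
        rows.append(
            {
                "frame": frame,
                "vertex_id": vid,
                "x": p0[0],
                "y": p0[1],
                "m": m,
                "theta": theta,
            }
        )
    return pd.DataFrame(
        rows, columns=["frame", "vertex_id", "x", "y", "m", "theta"]
    )


def grid_average_anisotropy(
    table: pd.DataFrame, spacing: float = 20.0,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Average per-vertex nematic tensors on a square grid.

    Tensors (not angles) are averaged count-weighted per grid cell, then
    (m, theta) re-extracted; two orthogonal nematics of equal magnitude
    cancel.  The grid is anchored at the bounding-box origin of the input
    unless ``origin`` is given.  Default spacing 20 um.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if origin is None:
        origin = (table["x"].min(), table["y"].min())
    df = table.copy()
    df["gx"] = np.floor((df["x"] - origin[0]) / spacing).astype(int)
    df["gy"] = np.floor((df["y"] - origin[1]) / spacing).astype(int)
    # nematic tensor components of each vertex
    df["qxx"] = df["m"] * np.cos(2 * df["theta"]) / 2
    df["qxy"] = df["m"] * np.sin(2 * df["theta"]) / 2
    rows = []
    for (gx, gy), grp in df.groupby(["gx", "gy"]):
        qxx, qxy = grp["qxx"].mean(), grp["qxy"].mean()
        m = 2 * math.hypot(qxx, qxy)
        theta = 0.5 * math.atan2(2 * qxy, 2 * qxx) % math.pi if m > 0 else float("nan")
        rows.append(
            {
                "gx": gx,
                "gy": gy,
                "m": m,
                "theta_deg": math.degrees(theta) if m > 0 else float("nan"),
                "count": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["gx", "gy", "m", "theta_deg", "count"])


def vertex_tension_nodes(
    mesh: CellMesh, vertex_id: int
) -> tuple[list[int], np.ndarray]:
    """Tension-triangulation nodes of the three cells at a vertex, in
    physical orientation.

    Returns ``(cell_ids, nodes)`` where ``nodes[k]`` is the tension-space
    position (up to translation) of the cell between the k-th and (k+1)-th
    interface in counter-clockwise order.  Successive node differences are
    the interface tension vectors rotated by +90 degrees, so on a mesh that
    is exactly the Voronoi diagram of its tension triangulation the nodes
    reproduce the generating points.
    """
    angles, eids = mesh.vertex_angles(vertex_id)
    t = infer_vertex_tensions(angles)
    p0 = mesh.position(vertex_id)
    units = []
    for eid in eids:
        u, v = mesh.interfaces[eid].vertex_pair
        other = v if u == vertex_id else u
        d = mesh.position(other) - p0
        units.append(d / np.linalg.norm(d))
    # cell k sits in the sector between edges k and k+1
    cells = []
    for k in range(3):
        e1, e2 = eids[k], eids[(k + 1) % 3]
        shared = set(mesh.interfaces[e1].cell_pair) & set(
            mesh.interfaces[e2].cell_pair
        )
        shared.discard(-1)
        if len(shared) != 1:
            raise InferenceUndefinedError(
                f"vertex {vertex_id}: ambiguous cell sector between edges "
                f"{e1} and {e2}"
            )
        cells.append(shared.pop())
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90 deg
    nodes = np.zeros((3, 2))
    for k in (1, 2):
        nodes[k] = nodes[k - 1] + rot @ (t[k] * units[k])
    return cells, nodes
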