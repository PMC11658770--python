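"""Planar, tracked polygonal cell meshes.

The central container is :class:`CellMesh`: a single time frame of a
segmented epithelium represented as a straight-interface polygonal cell
array.  Cells are simple polygons given by counter-clockwise vertex loops;
interfaces (cell-cell junctions) are derived from the loops, never stored.
A :class:`TrackedSequence` is a time-ordered list of frames in which cell
ids are persistent tracking ids.

Coordinates are planar, in micrometres, with the anterior-posterior axis
along +x and the dorso-ventral axis along +y.  Angles are handled in
radians internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon

#: Sentinel cell id used on the outer side of boundary interfaces.
BOUNDARY = -1

SCHEMA = "tigon-mesh-1"


class MeshValidationError(ValueError):
    """A mesh invariant is violated; the message names the offending entity."""


@dataclass(frozen=True)
class Interface:
    """A straight cell-cell junction segment.

    ``vertex_pair`` is ordered (u, v) with u < v; ``cell_pair`` is
    (left cell of u->v, right cell of u->v), using :data:`BOUNDARY` for a
    missing neighbour.  The direction vector points from u to v and has
    length equal to the interface length.
    """

    id: int
    vertex_pair: tuple[int, int]
    cell_pair: tuple[int, int]

    @property
    def is_boundary(self) -> bool:
        return BOUNDARY in self.cell_pair


@dataclass
class Cell:
    id: int
    vertex_loop: list[int]
    label: str = ""


class CellMesh:
    """One frame of a polygonal cell array.

    Parameters
    ----------
    vertices
        Mapping of vertex id to (x, y) position in micrometres.
    cells
        Mapping of cell id to :class:`Cell` (or to a bare vertex loop).
    frame_time
        Time of the frame in minutes.
    """

    def __init__(
        self,
        vertices: Mapping[int, Sequence[float]],
        cells: Mapping[int, Cell | Sequence[int]],
        frame_time: float = 0.0,
    ):
        self.frame_time = float(frame_time)
        self.vertices: dict[int, np.ndarray] = {
            int(k): np.asarray(v, dtype=float) for k, v in vertices.items()
        }
        self.cells: dict[int, Cell] = {}
        for cid, c in cells.items():
            cid = int(cid)
            if isinstance(c, Cell):
                self.cells[cid] = Cell(cid, [int(v) for v in c.vertex_loop], c.label)
            else:
                self.cells[cid] = Cell(cid, [int(v) for v in c])
        self._build_interfaces()

    # ------------------------------------------------------------------ build

    def _build_interfaces(self) -> None:
        # Edge (u, v) appearing in a CCW loop means that cell lies to the
        # left of u->v; the partner cell contributes (v, u).
        left_of: dict[tuple[int, int], int] = {}
        for cid, cell in self.cells.items():
            loop = cell.vertex_loop
            for a, b in zip(loop, loop[1:] + loop[:1]):
                if (a, b) in left_of:
                    raise MeshValidationError(
                        f"directed edge ({a},{b}) claimed by cells "
                        f"{left_of[(a, b)]} and {cid}"
                    )
                left_of[(a, b)] = cid

        self.interfaces: dict[int, Interface] = {}
        self._edge_index: dict[tuple[int, int], int] = {}
        for eid, (u, v) in enumerate(
            sorted({(min(a, b), max(a, b)) for a, b in left_of})
        ):
            ca = left_of.get((u, v), BOUNDARY)
            cb = left_of.get((v, u), BOUNDARY)
            self.interfaces[eid] = Interface(eid, (u, v), (ca, cb))
            self._edge_index[(u, v)] = eid

        self._vertex_edges: dict[int, list[int]] = {v: [] for v in self.vertices}
        for eid, itf in self.interfaces.items():
            for v in itf.vertex_pair:
                self._vertex_edges[v].append(eid)

    # ------------------------------------------------------------- geometry

    def position(self, vertex_id: int) -> np.ndarray:
        return self.vertices[vertex_id]

    def interface_vector(self, interface_id: int) -> np.ndarray:
        """Vector from the first to the second vertex of the interface."""
        u, v = self.interfaces[interface_id].vertex_pair
        return self.vertices[v] - self.vertices[u]

    def interface_length(self, interface_id: int) -> float:
        return float(np.linalg.norm(self.interface_vector(interface_id)))

    def interface_between(self, cell_a: int, cell_b: int) -> int | None:
        pair = {cell_a, cell_b}
        for eid, itf in self.interfaces.items():
            if set(itf.cell_pair) == pair:
                return eid
        return None

    def cell_polygon(self, cell_id: int) -> np.ndarray:
        loop = self.cells[cell_id].vertex_loop
        return np.array([self.vertices[v] for v in loop])

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        """Area centroid of the cell polygon."""
        p = Polygon(self.cell_polygon(cell_id))
        return np.array([p.centroid.x, p.centroid.y])

    def cell_area(self, cell_id: int) -> float:
        return float(Polygon(self.cell_polygon(cell_id)).area)

    # ------------------------------------------------------------- topology

    def vertex_degree(self, vertex_id: int) -> int:
        return len(self._vertex_edges[vertex_id])

    def edges_at_vertex(self, vertex_id: int) -> list[int]:
        return list(self._vertex_edges[vertex_id])

    def cells_at_vertex(self, vertex_id: int) -> set[int]:
        out: set[int] = set()
        for eid in self._vertex_edges[vertex_id]:
            out.update(self.interfaces[eid].cell_pair)
        out.discard(BOUNDARY)
        return out

    def is_boundary_vertex(self, vertex_id: int) -> bool:
        return any(
            self.interfaces[eid].is_boundary for eid in self._vertex_edges[vertex_id]
        )

    def is_boundary_cell(self, cell_id: int) -> bool:
        loop = self.cells[cell_id].vertex_loop
        for a, b in zip(loop, loop[1:] + loop[:1]):
            eid = self._edge_index[(min(a, b), max(a, b))]
            if self.interfaces[eid].is_boundary:
                return True
        return False

    def interior_vertices(self, degree: int | None = 3) -> list[int]:
        """Vertices not incident to any boundary interface.

        With ``degree=3`` (the default) transient fourfold/rosette vertices
        are excluded as well, matching the convention used by all inference
        and decomposition operations.
        """
        out = []
        for v in self.vertices:
            if self.vertex_degree(v) < 3 or self.is_boundary_vertex(v):
                continue
            if degree is not None and self.vertex_degree(v) != degree:
                continue
            out.append(v)
        return out

    def fourfold_vertices(self) -> list[int]:
        """Vertices of degree >= 4, flagged as transient configurations."""
        return [v for v in self.vertices if self.vertex_degree(v) >= 4]

    def adjacency(self) -> set[frozenset[int]]:
        """Set of adjacent cell-id pairs (boundary sentinel excluded)."""
        return {
            frozenset(itf.cell_pair)
            for itf in self.interfaces.values()
            if not itf.is_boundary
        }

    def euler_characteristic(self) -> int:
        """V - E + F including the outer face (2 for a disk-like mesh)."""
        return len(self.vertices) - len(self.interfaces) + len(self.cells) + 1

    # ------------------------------------------------------------ operations

    def vertex_angles(self, vertex_id: int) -> tuple[np.ndarray, list[int]]:
        """Angles between cyclically adjacent interfaces at a vertex.

        Returns ``(angles, edge_ids)`` where ``angles[i]`` is the positive
        angle (radians) swept counter-clockwise from ``edge_ids[i]`` to
        ``edge_ids[i + 1]``; the angles sum to 2*pi.

        Raises
        ------
        MeshValidationError
            If the vertex has degree < 3 (dangling vertex).
        """
        eids = self._vertex_edges[vertex_id]
        if len(eids) < 3:
            raise MeshValidationError(
                f"vertex {vertex_id} has degree {len(eids)} < 3"
            )
        p0 = self.vertices[vertex_id]
        dirs = []
        for eid in eids:
            u, v = self.interfaces[eid].vertex_pair
            other = v if u == vertex_id else u
            d = self.vertices[other] - p0
            dirs.append(math.atan2(d[1], d[0]))
        order = np.argsort(dirs)
        eids_sorted = [eids[i] for i in order]
        th = np.array([dirs[i] for i in order])
        angles = np.diff(np.append(th, th[0] + 2 * math.pi))
        return angles, eids_sorted

    def quartet_of_edge(self, interface_id: int) -> "Quartet":
        """The four cells and five interfaces of an edge's kite neighbourhood.

        The interface must be interior with both end vertices of degree 3.
        Returns a :class:`Quartet` whose ``cells`` are ordered
        (left-of-edge, right-of-edge, apex at first vertex, apex at second
        vertex) and whose ``flank_edges`` are the four flanking interfaces,
        paired per end vertex.
        """
        itf = self.interfaces[interface_id]
        if itf.is_boundary:
            raise MeshValidationError(f"interface {interface_id} is a boundary edge")
        u, v = itf.vertex_pair
        for w in (u, v):
            if self.vertex_degree(w) != 3:
                raise MeshValidationError(
                    f"end vertex {w} of interface {interface_id} has degree "
                    f"{self.vertex_degree(w)} != 3"
                )
        ca, cb = itf.cell_pair
        flank_u = [e for e in self._vertex_edges[u] if e != interface_id]
        flank_v = [e for e in self._vertex_edges[v] if e != interface_id]
        apex_u = self.cells_at_vertex(u) - {ca, cb}
        apex_v = self.cells_at_vertex(v) - {ca, cb}
        if len(apex_u) != 1 or len(apex_v) != 1:
            raise MeshValidationError(
                f"interface {interface_id}: kite neighbourhood touches the "
                "mesh boundary"
            )
        return Quartet(
            edge=interface_id,
            cells=(ca, cb, apex_u.pop(), apex_v.pop()),
            flank_edges=(flank_u[0], flank_u[1], flank_v[0], flank_v[1]),
            end_vertices=(u, v),
        )

    # ------------------------------------------------------------ validation

    def validate(self, angle_tol: float = 1e-6) -> None:
        """Check all mesh invariants, raising on the first violation."""
        for vid, p in self.vertices.items():
            if not np.all(np.isfinite(p)):
                raise MeshValidationError(f"vertex {vid} has non-finite position")
        for cid, cell in self.cells.items():
            if len(cell.vertex_loop) < 3:
                raise MeshValidationError(f"cell {cid} has fewer than 3 vertices")
            if len(set(cell.vertex_loop)) != len(cell.vertex_loop):
                raise MeshValidationError(f"cell {cid} repeats a vertex in its loop")
            poly = Polygon(self.cell_polygon(cid))
            if not poly.is_valid:
                raise MeshValidationError(
                    f"cell {cid}: vertex loop is not a simple polygon"
                )
            if _signed_area(self.cell_polygon(cid)) <= 0:
                raise MeshValidationError(
                    f"cell {cid}: vertex loop is not counter-clockwise "
                    "(non-positive signed area)"
                )
        for eid, itf in self.interfaces.items():
            u, v = itf.vertex_pair
            if not itf.is_boundary and u == v:
                raise MeshValidationError(f"interface {eid} is degenerate")
        for vid in self.vertices:
            if self.vertex_degree(vid) == 0:
                raise MeshValidationError(f"vertex {vid} is isolated")
            if not self.is_boundary_vertex(vid) and self.vertex_degree(vid) >= 3:
                angles, _ = self.vertex_angles(vid)
                if abs(float(np.sum(angles)) - 2 * math.pi) > angle_tol:
                    raise MeshValidationError(
                        f"vertex {vid}: interface angles sum to "
                        f"{np.sum(angles)} != 2*pi"
                    )


@dataclass(frozen=True)
class Quartet:
    """Kite neighbourhood of an interior interface.

    ``cells`` = (cell left of the edge, cell right of the edge, apex cell at
    the first end vertex, apex cell at the second); ``flank_edges`` = the two
    flanking interfaces at the first end vertex followed by the two at the
    second.
    """

    edge: int
    cells: tuple[int, int, int, int]
    flank_edges: tuple[int, int, int, int]
    end_vertices: tuple[int, int]


@dataclass
class TrackedSequence:
    """Time-ordered frames with persistent cell (tracking) ids."""

    frames: list[CellMesh] = field(default_factory=list)

    def __post_init__(self):
        times = [f.frame_time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise MeshValidationError("frame times are not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def validate(self) -> None:
        for i, f in enumerate(self.frames):
            try:
                f.validate()
            except MeshValidationError as e:
                raise MeshValidationError(f"frame {i}: {e}") from e


# ---------------------------------------------------------------------- I/O


def read_mesh_json(path) -> TrackedSequence:
    """Read a tracked sequence from the ``tigon-mesh-1`` JSON format.

    All mesh invariants are validated on read; violations raise
    :class:`MeshValidationError` naming the frame and entity.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise MeshValidationError(f"{path}: malformed JSON ({e})") from e
    if doc.get("schema") != SCHEMA:
        raise MeshValidationError(
            f"{path}: unknown schema {doc.get('schema')!r}, expected {SCHEMA!r}"
        )
    frames = []
    for fr in doc["frames"]:
        cells = {
            int(cid): Cell(int(cid), [int(v) for v in c["vertex_loop"]],
                           c.get("label", ""))
            for cid, c in fr["cells"].items()
        }
        frames.append(
            CellMesh(
                {int(k): v for k, v in fr["vertices"].items()},
                cells,
                frame_time=fr.get("time_min", 0.0),
            )
        )
    seq = TrackedSequence(frames)
    seq.validate()
    return seq


def write_mesh_json(seq: TrackedSequence | CellMesh, path) -> None:
    """Write a sequence (or single frame) so that read(write(x)) == x.

    Coordinates survive at full float precision; output is byte-stable
    (sorted keys, fixed separators).
    """
    if isinstance(seq, CellMesh):
        seq = TrackedSequence([seq])
    doc = {
        "schema": SCHEMA,
        "frames": [
            {
                "time_min": f.frame_time,
                "vertices": {str(k): [float(x) for x in v]
                             for k, v in f.vertices.items()},
                "cells": {
                    str(cid): {"vertex_loop": c.vertex_loop, "label": c.label}
                    for cid, c in f.cells.items()
                },
            }
            for f in seq.frames
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def interfaces_table(mesh: CellMesh, frame: int = 0):
    """Per-interface table: frame, edge_id, cell_a, cell_b, length_um, angle_deg."""
    import pandas as pd

    rows = []
    for eid, itf in mesh.interfaces.items():
        vec = mesh.interface_vector(eid)
        rows.append(
            {
                "frame": frame,
                "edge_id": eid,
                "cell_a": itf.cell_pair[0],
                "cell_b": itf.cell_pair[1],
                "length_um": float(np.linalg.norm(vec)),
                "angle_deg": math.degrees(math.atan2(vec[1], vec[0])) % 180.0,
            }
        )
    return pd.DataFrame(rows)


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def mesh_from_cells(
    cell_loops: Mapping[int, Sequence[Sequence[float]]],
    labels: Mapping[int, str] | None = None,
    frame_time: float = 0.0,
    tol: float = 1e-9,
) -> CellMesh:
    """Build a :class:`CellMesh` from per-cell coordinate loops.

    Vertices shared between cells are merged when closer than ``tol``.
    Convenience constructor used by the synthetic generator and the label
    image extractor.
    """
    key_of: dict[tuple[int, int], int] = {}
    verts: dict[int, np.ndarray] = {}
    scale = 1.0 / tol

    def vid(p) -> int:
        key = (round(p[0] * scale), round(p[1] * scale))
        if key not in key_of:
            key_of[key] = len(key_of)
            verts[key_of[key]] = np.asarray(p, dtype=float)
        return key_of[key]

    cells = {}
    for cid, loop in cell_loops.items():
        ids = [vid(p) for p in loop]
        # drop consecutive duplicates produced by merging
        dedup = [v for i, v in enumerate(ids) if v != ids[i - 1]]
        cells[cid] = Cell(cid, dedup, (labels or {}).get(cid, ""))
    return CellMesh(verts, cells, frame_time=frame_time)
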