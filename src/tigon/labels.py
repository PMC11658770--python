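"""Extract polygonal cell meshes from 2D integer label images.

This is a stand-in for an upstream segmentation/tracking pipeline: each
labelled region becomes one cell, vertices are placed where three or more
labels (counting background 0) meet, and interfaces are the straight
segments between consecutive vertices along shared boundaries.  Interface
curvature present in the raster is discarded, consistent with the
straight-interface representation used throughout.

Limitations: cells are assumed star-shaped around their centroid (vertex
loops are ordered by angle), which holds for the near-convex cells of
epithelial segmentations this is meant for.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np

from .mesh import CellMesh, MeshValidationError, TrackedSequence, mesh_from_cells


def mesh_from_labels(
    image: np.ndarray,
    pixel_size: float = 1.0,
    frame_time: float = 0.0,
) -> CellMesh:
    """Build a :class:`~tigon.mesh.CellMesh` from a 2D label image.

    Parameters
    ----------
    image
        2D integer array; 0 is background/boundary, each positive label one
        contiguous cell region.
    pixel_size
        Physical size of one pixel in micrometres.

    Raises
    ------
    MeshValidationError
        If a label's region is not contiguous (the message lists the label).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise MeshValidationError("label image must be 2D")
    img = np.pad(img, 1, constant_values=0)

    _check_contiguous(img)

    # Junction candidates: lattice corners whose four surrounding pixels
    # carry >= 3 distinct values (background counts).
    blocks = np.stack(
        [img[:-1, :-1], img[:-1, 1:], img[1:, :-1], img[1:, 1:]], axis=-1
    )
    srt = np.sort(blocks, axis=-1)
    ndistinct = 1 + np.sum(srt[..., 1:] != srt[..., :-1], axis=-1)
    jr, jc = np.nonzero(ndistinct >= 3)

    # Cluster adjacent junction corners (a tri-junction in a raster can fire
    # on a couple of neighbouring corners) and average their positions.
    clusters = _cluster_points(np.stack([jr, jc], axis=1), radius=1.5)
    vertices: list[np.ndarray] = []
    vertex_labels: list[set[int]] = []
    for idxs in clusters:
        pts = np.stack([jr[idxs], jc[idxs]]).T
        labs: set[int] = set()
        for r, c in pts:
            labs.update(int(x) for x in blocks[r, c])
        # corner (r, c) sits between pixel centres; x = column, y = row
        pos = pts.mean(axis=0) + 0.5
        vertices.append(np.array([pos[1], pos[0]]) * pixel_size)
        vertex_labels.append(labs)

    labels_present = sorted(int(l) for l in np.unique(img) if l != 0)
    loops: dict[int, list[np.ndarray]] = {}
    for lab in labels_present:
        idxs = [i for i, labs in enumerate(vertex_labels) if lab in labs]
        if len(idxs) < 3:
            raise MeshValidationError(
                f"label {lab}: fewer than 3 junction vertices found"
            )
        rr, cc = np.nonzero(img == lab)
        centroid = np.array([cc.mean() + 0.5, rr.mean() + 0.5]) * pixel_size
        idxs.sort(
            key=lambda i: math.atan2(*(vertices[i] - centroid)[::-1])
        )
        loops[lab] = [vertices[i] for i in idxs]

    mesh = mesh_from_cells(loops, frame_time=frame_time, tol=1e-9)
    return mesh


def read_labels_sequence(manifest_path) -> TrackedSequence:
    """Read a tracked sequence from a frame-index manifest.

    The manifest is a CSV with columns ``frame,file,time_min``; files are
    2D TIFF/PNG label images whose integer labels are the persistent cell
    tracking ids.  Pixel size defaults to 1 um; rescale afterwards if
    needed.
    """
    from skimage.io import imread

    manifest_path = Path(manifest_path)
    frames = []
    with open(manifest_path) as fh:
        rows = sorted(csv.DictReader(fh), key=lambda r: int(r["frame"]))
    for row in rows:
        img = imread(manifest_path.parent / row["file"])
        frames.append(mesh_from_labels(img, frame_time=float(row["time_min"])))
    return TrackedSequence(frames)


def _check_contiguous(img: np.ndarray) -> None:
    from skimage.measure import label as cc_label

    bad = []
    for lab in np.unique(img):
        if lab == 0:
            continue
        ncomp = cc_label(img == lab, connectivity=2).max()
        if ncomp > 1:
            bad.append(int(lab))
    if bad:
        raise MeshValidationError(f"non-contiguous label regions: {bad}")


def _cluster_points(pts: np.ndarray, radius: float) -> list[list[int]]:
    """Single-linkage clusters of 2D integer points within ``radius``."""
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    r2 = radius * radius
    # junction sets are tiny; quadratic linkage is fine
    for i in range(n):
        for j in range(i + 1, n):
            d = pts[i] - pts[j]
            if d[0] * d[0] + d[1] * d[1] <= r2:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())
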