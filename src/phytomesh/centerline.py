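"""Leaf length along the midline of a twisted leaf.

Botanical leaf length is measured along the line through the middle of
the blade.  On a flat leaf the surface shortest path between base and tip
is a fine proxy, but on a strongly twisted leaf (the *Welwitschia* case)
the shortest path hugs one margin and undercuts the midline.  The
estimator here recovers the midline in five steps:

1. find the leaf's outer edges (boundary loops), optionally excluding a
   neighbourhood of the start and end points;
2. map every vertex's distance to those edges (Fast Marching) — the
   ridge of this field is the midline;
3. map every vertex's distance from the starting point (Fast Marching)
   and cut the leaf into ``k`` bands of equal distance;
4. in every band except the two containing the start and end, take the
   vertex farthest from the edges — a midline waypoint;
5. chain shortest paths start → waypoints (in band order) → end and sum
   their lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BandPartitionError, PhytomeshError
from .geodesics import (
    EdgeGraph,
    GeodesicPath,
    ScalarField,
    build_edge_graph,
    dijkstra_field,
    dijkstra_path,
    fmm_distance,
)
from .mesh import TriangleMesh, boundary_loops

__all__ = [
    "CenterlineResult",
    "leaf_edge_set",
    "edge_distance_field",
    "band_partition",
    "band_waypoints",
    "centerline_length",
    "snap_to_vertex",
]


@dataclass
class CenterlineResult:
    """Everything the five-step estimator produced."""

    band_count: int
    waypoints: list[int]  # one per interior band, in band order
    path: GeodesicPath  # start -> waypoints -> end, concatenated
    length: float  # mm
    segment_lengths: list[float]
    edge_field: ScalarField
    source_field: ScalarField
    bands: np.ndarray


def snap_to_vertex(mesh: TriangleMesh, point) -> int:
    """Index of the mesh vertex nearest (Euclidean) to an arbitrary 3D point."""
    p = np.asarray(point, dtype=float).reshape(3)
    return int(np.argmin(np.linalg.norm(mesh.vertices - p[None, :], axis=1)))


def leaf_edge_set(
    mesh: TriangleMesh,
    start: int,
    end: int,
    exclusion_radius: float = 0.0,
    graph: EdgeGraph | None = None,
) -> set[int]:
    """Boundary vertices of the leaf, minus neighbourhoods of start and end.

    The exclusion radius is measured as graph (edge-path) distance; it
    exists so that an attachment scar or cut at either end of the leaf is
    not mistaken for leaf margin.
    """
    loops = boundary_loops(mesh)
    if not loops:
        raise PhytomeshError("no outer edges: the mesh is closed")
    edge_vertices: set[int] = set()
    for loop in loops:
        edge_vertices.update(loop.vertices)
    if exclusion_radius > 0.0:
        g = graph or build_edge_graph(mesh)
        near = dijkstra_field(mesh, [start, end], graph=g).values
        edge_vertices = {v for v in edge_vertices if near[v] > exclusion_radius}
    if not edge_vertices:
        raise PhytomeshError(
            "exclusion radius removed every boundary vertex; use a smaller radius"
        )
    return edge_vertices


def edge_distance_field(mesh: TriangleMesh, edges) -> ScalarField:
    """Fast-Marching distance from every vertex to the leaf edge set."""
    f = fmm_distance(mesh, edges)
    f.provenance = "edge map"
    return f


def band_partition(source_field: ScalarField, end: int, k: int) -> np.ndarray:
    """Cut the leaf into ``k`` bands of equal source-distance.

    Band ``i`` collects vertices whose distance from the start lies in
    ``[i·D/k, (i+1)·D/k)`` where ``D`` is the distance at the end point;
    vertices beyond ``D`` (behind the end point) join the last band.
    Every band between the start's and the end's must be populated,
    otherwise ``k`` is too large for the mesh resolution.
    """
    if k < 3:
        raise ValueError("band count k must be at least 3")
    D = float(source_field.values[end])
    if not np.isfinite(D) or D <= 0.0:
        raise PhytomeshError(
            "source-distance field is not finite and positive at the end point"
        )
    width = D / k
    bands = np.floor(source_field.values / width).astype(np.int64)
    bands = np.clip(bands, 0, k - 1)
    bands[~np.isfinite(source_field.values)] = k - 1
    end_band = int(bands[end])
    for i in range(0, end_band + 1):
        if not (bands == i).any():
            raise BandPartitionError(
                f"band {i} of {k} is empty: k too large for mesh resolution"
            )
    return bands


def band_waypoints(
    edge_field: ScalarField, bands: np.ndarray, start: int, end: int
) -> list[int]:
    """Farthest-from-edge vertex per band, skipping the start/end bands.

    Ties are broken toward the lowest vertex index (``argmax`` semantics),
    making the estimator deterministic.
    """
    skip = {int(bands[start]), int(bands[end])}
    waypoints = []
    for band in range(int(bands.max()) + 1):
        if band in skip:
            continue
        members = np.flatnonzero(bands == band)
        if len(members) == 0:
            continue
        waypoints.append(int(members[np.argmax(edge_field.values[members])]))
    return waypoints


def centerline_length(
    mesh: TriangleMesh,
    start: int,
    end: int,
    k: int = 10,
    exclusion_radius: float = 0.0,
) -> CenterlineResult:
    """Run the full five-step midline estimator.

    The returned length is the sum of the chained shortest-path segments
    and is, by construction, at least the plain shortest-path length
    between start and end.
    """
    g = build_edge_graph(mesh)
    edges = leaf_edge_set(mesh, start, end, exclusion_radius, graph=g)
    edge_field = edge_distance_field(mesh, edges)
    source_field = fmm_distance(mesh, [start])
    source_field.provenance = "source map"
    bands = band_partition(source_field, end, k)
    waypoints = band_waypoints(edge_field, bands, start, end)
    # order along the leaf follows the band index
    waypoints.sort(key=lambda v: int(bands[v]))

    chain = [start, *waypoints, end]
    full: list[int] = [start]
    seg_lengths: list[float] = []
    total = 0.0
    for a, b in zip(chain[:-1], chain[1:]):
        seg = dijkstra_path(mesh, a, b, graph=g)
        seg_lengths.append(seg.length)
        total += seg.length
        full.extend(seg.vertices[1:])
    return CenterlineResult(
        band_count=k,
        waypoints=waypoints,
        path=GeodesicPath(vertices=full, length=total),
        length=total,
        segment_lengths=seg_lengths,
        edge_field=edge_field,
        source_field=source_field,
        bands=bands,
    )
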