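"""Triangle-mesh data model, I/O and whole-mesh morphometrics.

The mesh is the universal substrate of scan-based plant phenotyping:
structured-light scanners deliver a point cloud that is triangulated into a
surface, and every quantity of botanical interest — leaf area, enclosed
volume, the surface-to-volume (S/V) ratio of a succulent, path lengths on
the surface — is computed from that triangulation.  Coordinates are taken
to be millimetres throughout; areas are mm², volumes mm³, S/V mm⁻¹.

Conventions
-----------
* vertex indices are 0-based everywhere inside the package; OBJ's 1-based
  indices are converted at the I/O boundary only;
* an *edge* is an unordered vertex pair; a manifold edge borders at most
  two faces; a *closed* mesh has no edge bordering exactly one face;
* ``enclosed_volume`` is defined only for closed, edge-manifold meshes and
  re-orients faces consistently (breadth-first flood fill over shared
  edges, then a global flip if the signed volume comes out negative)
  before summing signed tetrahedra.
"""

from __future__ import annotations

import json
import os
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _connected_components

from .errors import EmptyMeshError, MeshParseError, NonManifoldError, OpenMeshError

__all__ = [
    "TriangleMesh",
    "BoundaryLoop",
    "MorphometricReport",
    "ValidationReport",
    "load_mesh",
    "save_mesh",
    "validate_mesh",
    "surface_area",
    "enclosed_volume",
    "sv_ratio",
    "boundary_loops",
    "mean_edge_length",
    "orient_faces",
    "measure",
]


class TriangleMesh:
    """Vertex positions (mm) plus triangle connectivity.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array, 0-based vertex indices
    attributes : optional dict of per-vertex arrays (generator metadata,
        colours, ...) carried along untouched.
    """

    def __init__(self, vertices, faces, attributes=None):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64).reshape(-1, 3)
        self.attributes: dict[str, np.ndarray] = dict(attributes or {})
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 2] == self.faces[:, 0])
            )
            if same.any():
                raise ValueError(
                    f"{int(same.sum())} topologically degenerate faces "
                    "(repeated vertex within a face)"
                )
        self._cache: dict[str, object] = {}

    # ------------------------------------------------------------------ basics
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return self.n_vertices == 0 or self.n_faces == 0

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: np.array(v) for k, v in self.attributes.items()},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TriangleMesh({self.n_vertices} vertices, {self.n_faces} faces)"

    # ------------------------------------------------------------------ edges
    def _edges_sorted(self) -> np.ndarray:
        """All face edges as sorted (lo, hi) pairs, 3 per face."""
        if "edges_sorted" not in self._cache:
            e = np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            self._cache["edges_sorted"] = np.sort(e, axis=1)
        return self._cache["edges_sorted"]

    def unique_edges(self):
        """(unique (k,2) edge array, per-edge face-border count)."""
        if "unique_edges" not in self._cache:
            uniq, counts = np.unique(self._edges_sorted(), axis=0, return_counts=True)
            self._cache["unique_edges"] = (uniq, counts)
        return self._cache["unique_edges"]

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.unique_edges()
        return uniq[counts == 1]


# ---------------------------------------------------------------------- types
@dataclass
class BoundaryLoop:
    """A closed cycle of boundary edges — a leaf margin or a thorn hole.

    ``vertices`` are ordered so that consecutive entries (cyclically) share
    a boundary edge, traversed in the direction the adjacent face uses; the
    loop therefore winds consistently with the surface orientation.
    """

    vertices: list[int]
    perimeter: float

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class ValidationReport:
    is_manifold: bool
    is_closed: bool
    is_consistently_oriented: bool
    boundary_edge_count: int
    connected_component_count: int
    euler_characteristic: int
    n_vertices: int
    n_faces: int
    degenerate_face_indices: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MorphometricReport:
    """One Table-style row of whole-mesh measurements.

    ``volume`` and ``sv_ratio`` are ``None`` for open surfaces, where an
    enclosed volume is undefined.
    """

    vertex_count: int
    face_count: int
    mean_edge_length: float
    area: float
    volume: float | None = None
    sv_ratio: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_csv_row(self, header: bool = True) -> str:
        cols = ["vertices", "faces", "mean_edge_length", "area", "volume", "sv_ratio"]
        vals = [
            self.vertex_count,
            self.face_count,
            self.mean_edge_length,
            self.area,
            "" if self.volume is None else self.volume,
            "" if self.sv_ratio is None else self.sv_ratio,
        ]
        row = ",".join(str(v) for v in vals)
        return (",".join(cols) + "\n" + row) if header else row


# ------------------------------------------------------------------------ I/O
_FORMATS = ("ply", "obj", "stl")


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices that are bitwise-identical (STL triangle soup)."""
    view = vertices.view([("x", np.float64), ("y", np.float64), ("z", np.float64)])
    _, first, inverse = np.unique(view, return_index=True, return_inverse=True)
    # keep first-occurrence order so vertex numbering is stable
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse.ravel()][faces]


def _drop_unreferenced(vertices, faces, attributes=None):
    used = np.zeros(len(vertices), dtype=bool)
    used[faces.ravel()] = True
    remap = np.cumsum(used) - 1
    attrs = {k: np.asarray(v)[used] for k, v in (attributes or {}).items()}
    return vertices[used], remap[faces], attrs


def load_mesh(path, format: str = "auto") -> TriangleMesh:
    """Read a PLY / OBJ / STL surface into a :class:`TriangleMesh`.

    STL stores each triangle with its own three corners, so exact duplicate
    coordinates are welded on load; PLY and OBJ connectivity is taken as
    stored.  Unreferenced vertices are dropped for every format.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = path.suffix.lstrip(".").lower() if format == "auto" else format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    try:
        tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise MeshParseError(f"could not parse {path} as {fmt}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise EmptyMeshError(f"empty mesh in {path}")
    if fmt == "stl":
        vertices, faces = _weld_exact(vertices, faces)
    attrs = {}
    try:
        colors = tm.visual.vertex_colors
        if colors is not None and len(colors) == len(vertices) and fmt != "stl":
            attrs["color"] = np.asarray(colors).copy()
    except Exception:  # noqa: BLE001 - colour is pass-through only
        pass
    vertices, faces, attrs = _drop_unreferenced(vertices, faces, attrs)
    return TriangleMesh(vertices, faces, attrs)


def save_mesh(mesh: TriangleMesh, path, format: str = "auto", *, ascii: bool = False) -> None:
    """Write ``mesh`` to ``path`` (PLY / OBJ / STL).

    PLY and STL default to their binary (little-endian) encodings;
    ``ascii=True`` selects the text variants.  OBJ is always text.
    """
    if mesh.is_empty:
        raise EmptyMeshError("refusing to save an empty mesh")
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower() if format == "auto" else format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if "color" in mesh.attributes and fmt == "ply":
        tm.visual.vertex_colors = mesh.attributes["color"]
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii" if ascii else "binary")
    elif fmt == "stl":
        data = tm.export(file_type="stl_ascii" if ascii else "stl")
    else:
        data = tm.export(file_type="obj", include_texture=False)
    mode = "wb" if isinstance(data, bytes) else "w"
    if str(path.parent) not in ("", "."):
        os.makedirs(path.parent, exist_ok=True)
    with open(path, mode) as fh:
        fh.write(data)


# ----------------------------------------------------------------- validation
def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Topology / orientation report; always returns, never raises."""
    uniq, counts = mesh.unique_edges()
    boundary_count = int((counts == 1).sum())
    manifold = bool((counts <= 2).all())
    closed = manifold and boundary_count == 0

    # orientation: every interior edge must be traversed once in each direction
    directed = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    lo = directed.min(axis=1)
    hi = directed.max(axis=1)
    forward = directed[:, 0] == lo  # direction flag per half-edge
    key = lo.astype(np.int64) * mesh.n_vertices + hi
    order = np.argsort(key, kind="stable")
    k_s, f_s = key[order], forward[order]
    oriented = True
    if manifold:
        # group by edge: interior edges have exactly one forward + one backward
        uniq_k, start = np.unique(k_s, return_index=True)
        cnt = np.diff(np.append(start, len(k_s)))
        fsum = np.add.reduceat(f_s.astype(int), start)
        interior = cnt == 2
        oriented = bool((fsum[interior] == 1).all())
    else:
        oriented = False

    # connected components over the vertex graph
    if mesh.n_faces:
        u, v = uniq[:, 0], uniq[:, 1]
        adj = coo_matrix(
            (np.ones(len(u)), (u, v)), shape=(mesh.n_vertices, mesh.n_vertices)
        )
        ncomp, _ = _connected_components(adj, directed=False)
    else:
        ncomp = mesh.n_vertices

    p0 = mesh.vertices[mesh.faces[:, 0]]
    cross = np.cross(
        mesh.vertices[mesh.faces[:, 1]] - p0, mesh.vertices[mesh.faces[:, 2]] - p0
    )
    degen = np.flatnonzero(np.linalg.norm(cross, axis=1) <= 0.0)

    return ValidationReport(
        is_manifold=manifold,
        is_closed=closed,
        is_consistently_oriented=oriented,
        boundary_edge_count=boundary_count,
        connected_component_count=int(ncomp),
        euler_characteristic=int(mesh.n_vertices - len(uniq) + mesh.n_faces),
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        degenerate_face_indices=[int(i) for i in degen],
    )


# --------------------------------------------------------------- morphometrics
def surface_area(mesh: TriangleMesh) -> float:
    """Sum of triangle areas: half the magnitude of the edge cross products."""
    if mesh.is_empty:
        raise EmptyMeshError("surface area of an empty mesh")
    p0 = mesh.vertices[mesh.faces[:, 0]]
    cross = np.cross(
        mesh.vertices[mesh.faces[:, 1]] - p0, mesh.vertices[mesh.faces[:, 2]] - p0
    )
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def orient_faces(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy with consistent winding, outward for closed meshes.

    Faces are flipped by breadth-first flood fill across shared edges (each
    interior edge must be traversed in opposite directions by its two
    faces); for closed meshes the whole mesh is then flipped globally if the
    signed volume is negative.
    """
    uniq, counts = mesh.unique_edges()
    if (counts > 2).any():
        bad = uniq[counts > 2][0]
        raise NonManifoldError(
            f"edge ({bad[0]}, {bad[1]}) borders {int(counts.max())} faces"
        )
    faces = mesh.faces.copy()
    # adjacency: edge -> faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fid, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fid)

    def directed_edges(f):
        return ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))

    visited = np.zeros(len(faces), dtype=bool)
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        visited[seed] = True
        queue = deque([seed])
        while queue:
            fid = queue.popleft()
            for a, b in directed_edges(faces[fid]):
                for nb in edge_faces[(min(a, b), max(a, b))]:
                    if nb == fid or visited[nb]:
                        continue
                    # neighbour must traverse the shared edge as (b, a)
                    if (a, b) in directed_edges(faces[nb]):
                        faces[nb] = faces[nb][::-1]
                    visited[nb] = True
                    queue.append(nb)
    out = TriangleMesh(mesh.vertices.copy(), faces, dict(mesh.attributes))
    if not (counts == 1).any():  # closed: make the orientation outward
        if _signed_volume(out) < 0:
            out = TriangleMesh(
                out.vertices, out.faces[:, ::-1].copy(), dict(out.attributes)
            )
    return out


def _signed_volume(mesh: TriangleMesh) -> float:
    # tetrahedra are taken about the vertex centroid rather than the world
    # origin: the sum is origin-independent for closed surfaces, but the
    # centroid keeps the floating-point cancellation small for far-away meshes
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    p0 = v[mesh.faces[:, 0]]
    p1 = v[mesh.faces[:, 1]]
    p2 = v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume enclosed by a closed surface, via signed tetrahedra.

    The tetrahedra share the coordinate origin, but the summed signed
    volume of a closed, consistently oriented surface is independent of
    that choice (the divergence theorem), so the result is
    translation-invariant.
    """
    if mesh.is_empty:
        raise EmptyMeshError("volume of an empty mesh")
    rep = validate_mesh(mesh)
    if not rep.is_manifold:
        raise NonManifoldError("volume undefined for a non-manifold mesh")
    if rep.boundary_edge_count > 0:
        nloops = len(boundary_loops(mesh))
        raise OpenMeshError(
            f"volume undefined for open surface ({nloops} boundary loop"
            f"{'s' if nloops != 1 else ''})"
        )
    oriented = mesh if rep.is_consistently_oriented else orient_faces(mesh)
    return abs(_signed_volume(oriented))


def sv_ratio(mesh: TriangleMesh) -> float:
    """Surface-to-volume ratio (mm⁻¹), the classic succulence descriptor."""
    return surface_area(mesh) / enclosed_volume(mesh)


def mean_edge_length(mesh: TriangleMesh) -> float:
    """Mean Euclidean length over unique undirected edges (the resolution proxy)."""
    uniq, _ = mesh.unique_edges()
    if len(uniq) == 0:
        raise EmptyMeshError("mesh has no edges")
    d = mesh.vertices[uniq[:, 0]] - mesh.vertices[uniq[:, 1]]
    return float(np.linalg.norm(d, axis=1).mean())


def boundary_loops(mesh: TriangleMesh) -> list[BoundaryLoop]:
    """Closed cycles of boundary edges, each ordered along face winding."""
    uniq, counts = mesh.unique_edges()
    if (counts > 2).any():
        bad = uniq[counts > 2][0]
        raise NonManifoldError(
            f"edge ({bad[0]}, {bad[1]}) borders more than two faces"
        )
    boundary = set(map(tuple, uniq[counts == 1]))
    if not boundary:
        return []
    # recover the direction each boundary edge has inside its single face
    succ: dict[int, int] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if (min(a, b), max(a, b)) in boundary:
                succ[int(a)] = int(b)
    loops = []
    remaining = set(succ)
    while remaining:
        start = min(remaining)
        cycle = [start]
        remaining.discard(start)
        nxt = succ[start]
        while nxt != start:
            cycle.append(nxt)
            remaining.discard(nxt)
            nxt = succ[nxt]
        pts = mesh.vertices[cycle]
        per = float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())
        loops.append(BoundaryLoop(vertices=cycle, perimeter=per))
    return loops


def measure(mesh: TriangleMesh) -> MorphometricReport:
    """Full morphometric report; volume/S-V omitted on open surfaces."""
    rep = validate_mesh(mesh)
    vol = sv = None
    if rep.is_manifold and rep.is_closed:
        vol = enclosed_volume(mesh)
        sv = surface_area(mesh) / vol
    return MorphometricReport(
        vertex_count=mesh.n_vertices,
        face_count=mesh.n_faces,
        mean_edge_length=mean_edge_length(mesh),
        area=surface_area(mesh),
        volume=vol,
        sv_ratio=sv,
    )
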