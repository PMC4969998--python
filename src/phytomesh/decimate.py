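"""Mesh coarsening to a target mean edge length.

The resolution study needs a ladder of models of the *same* surface whose
only controlled difference is the mean distance between connected
vertices.  Coarsening is performed by iterated edge collapse:

* edges are processed shortest-first, which drives the edge-length
  distribution toward uniformity and makes the mean edge length — the
  study's independent variable — increase smoothly and monotonically;
* the surviving vertex of each collapse is placed at the minimiser of the
  accumulated quadric error (sum of squared distances to the planes of
  the faces the collapsed region originally carried).  Unlike snapping
  the vertex back onto the input surface, the quadric minimiser may sit
  marginally outside it, which keeps area *and* enclosed volume close to
  the input instead of systematically shrinking the model inside its own
  curvature;
* a collapse is rejected when it would change topology (link condition),
  pinch a boundary, or invert a surviving face, so closedness, boundary
  loop count and genus are preserved.

Boundary edges may only collapse along the boundary; an interior vertex
collapsing into a boundary vertex keeps the boundary vertex's position.
"""

from __future__ import annotations

import heapq

import numpy as np

from .errors import RemeshError
from .mesh import TriangleMesh

__all__ = ["collapse_to_mean_edge"]


def _vertex_quadrics(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Area-weighted fundamental error quadrics accumulated per vertex."""
    Q = np.zeros((len(V), 4, 4))
    p0, p1, p2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n, axis=1)
    ok = norm > 0
    unit = np.zeros_like(n)
    unit[ok] = n[ok] / norm[ok, None]
    d = -np.einsum("ij,ij->i", unit, p0)
    plane = np.concatenate([unit, d[:, None]], axis=1)
    K = plane[:, :, None] * plane[:, None, :] * (norm / 2.0)[:, None, None]
    for k in range(3):
        np.add.at(Q, F[:, k], K)
    return Q


def collapse_to_mean_edge(
    mesh: TriangleMesh, target: float, max_collapses: int | None = None
) -> TriangleMesh:
    """Collapse shortest edges until the mean edge length reaches ``target``.

    Raises :class:`RemeshError` when no further legal collapse exists
    before the target is reached (mesh too small, or topology constraints
    exhausted the candidate edges).
    """
    V = mesh.vertices.copy()
    F0 = mesh.faces
    n = len(V)
    faces: dict[int, tuple[int, int, int]] = {
        i: (int(a), int(b), int(c)) for i, (a, b, c) in enumerate(F0)
    }
    v2f: list[set[int]] = [set() for _ in range(n)]
    for fid, f in faces.items():
        for v in f:
            v2f[v].add(fid)
    Q = _vertex_quadrics(V, F0)
    alive = np.ones(n, dtype=bool)

    # boundary bookkeeping
    edge_use: dict[tuple[int, int], int] = {}
    for f in faces.values():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            e = (a, b) if a < b else (b, a)
            edge_use[e] = edge_use.get(e, 0) + 1
    on_boundary = np.zeros(n, dtype=bool)
    for (a, b), cnt in edge_use.items():
        if cnt == 1:
            on_boundary[a] = on_boundary[b] = True

    def neighbors(u: int) -> set[int]:
        s: set[int] = set()
        for fid in v2f[u]:
            s.update(faces[fid])
        s.discard(u)
        return s

    def is_boundary_edge(a: int, b: int) -> bool:
        shared = v2f[a] & v2f[b]
        return len(shared) == 1

    heap: list[tuple[float, int, int]] = []
    seen = set()
    for f in faces.values():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            e = (a, b) if a < b else (b, a)
            if e not in seen:
                seen.add(e)
                heap.append((float(np.linalg.norm(V[e[0]] - V[e[1]])), e[0], e[1]))
    heapq.heapify(heap)
    del seen

    def current_mean() -> float:
        fa = np.array(list(faces.values()), dtype=np.int64)
        e = np.sort(
            np.concatenate([fa[:, [0, 1]], fa[:, [1, 2]], fa[:, [2, 0]]]), axis=1
        )
        uniq = np.unique(e, axis=0)
        return float(
            np.linalg.norm(V[uniq[:, 0]] - V[uniq[:, 1]], axis=1).mean()
        )

    def placement(u: int, v: int) -> np.ndarray:
        ub, vb = on_boundary[u], on_boundary[v]
        if ub and not vb:
            return V[u]
        if vb and not ub:
            return V[v]
        if ub and vb:
            return 0.5 * (V[u] + V[v])
        q = Q[u] + Q[v]
        A = q[:3, :3]
        b = -q[:3, 3]
        mid = 0.5 * (V[u] + V[v])
        scale = np.trace(A)
        if scale <= 0:
            return mid
        try:
            x = np.linalg.solve(A + 1e-9 * scale * np.eye(3), b)
        except np.linalg.LinAlgError:
            return mid
        if np.linalg.norm(x - mid) > 2.0 * np.linalg.norm(V[u] - V[v]):
            return mid  # ill-conditioned quadric: stay local
        return x

    def face_normals_ok(u: int, pos: np.ndarray, skip: set[int]) -> bool:
        """Reject collapses that invert or squash any surviving face."""
        for fid in v2f[u]:
            if fid in skip:
                continue
            a, b, c = faces[fid]
            pa = pos if a == u else V[a]
            pb = pos if b == u else V[b]
            pc = pos if c == u else V[c]
            old0 = V[a], V[b], V[c]
            n_old = np.cross(old0[1] - old0[0], old0[2] - old0[0])
            n_new = np.cross(pb - pa, pc - pa)
            if np.dot(n_old, n_new) <= 0.0:
                return False
        return True

    mean = current_mean()
    if mean > target * 1.1:
        raise RemeshError(
            f"input mean edge length {mean:.3g} mm already exceeds the "
            f"target band around {target:.3g} mm (coarsening only)"
        )
    collapses = 0
    budget = max_collapses if max_collapses is not None else len(faces) * 2
    stop_at = 0.95 * target

    while mean < stop_at and heap:
        # small meshes move a lot per collapse: re-measure every time there
        recheck = max(1, len(faces) // 100) if len(faces) < 2000 else max(
            32, len(faces) // 100
        )
        batch = 0
        while batch < recheck and heap:
            w, u, v = heapq.heappop(heap)
            if not (alive[u] and alive[v]):
                continue
            if abs(float(np.linalg.norm(V[u] - V[v])) - w) > 1e-9:
                continue  # stale entry
            shared = v2f[u] & v2f[v]
            if len(shared) not in (1, 2):
                continue
            boundary_edge = len(shared) == 1
            if (on_boundary[u] and on_boundary[v]) and not boundary_edge:
                continue  # interior chord between boundary vertices: would pinch
            # link condition: common neighbours must be exactly the apexes
            opp: set[int] = set()
            for fid in shared:
                opp.update(faces[fid])
            opp -= {u, v}
            if neighbors(u) & neighbors(v) != opp:
                continue
            pos = placement(u, v)
            if not face_normals_ok(u, pos, shared) or not face_normals_ok(
                v, pos, shared
            ):
                continue
            # ---- commit
            V[u] = pos
            Q[u] = Q[u] + Q[v]
            on_boundary[u] = on_boundary[u] or on_boundary[v]
            alive[v] = False
            for fid in shared:
                for w_ in faces[fid]:
                    v2f[w_].discard(fid)
                del faces[fid]
            for fid in list(v2f[v]):
                a, b, c = faces[fid]
                faces[fid] = (
                    u if a == v else a,
                    u if b == v else b,
                    u if c == v else c,
                )
                v2f[u].add(fid)
            v2f[v].clear()
            for nb in neighbors(u):
                d = float(np.linalg.norm(V[u] - V[nb]))
                heapq.heappush(heap, (d, u, nb) if u < nb else (d, nb, u))
            collapses += 1
            batch += 1
            if collapses >= budget:
                break
        if not faces:
            raise RemeshError("collapsed the whole mesh before reaching the target")
        mean = current_mean()
        if batch == 0 or collapses >= budget:
            break

    if mean < 0.9 * target:
        raise RemeshError(
            f"could not reach target mean edge {target:.3g} mm; achieved "
            f"{mean:.3g} mm after {collapses} collapses"
        )

    used = sorted({v for f in faces.values() for v in f})
    remap = {v: i for i, v in enumerate(used)}
    newV = V[used]
    newF = np.array(
        [[remap[a], remap[b], remap[c]] for (a, b, c) in faces.values()],
        dtype=np.int64,
    )
    return TriangleMesh(newV, newF)
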