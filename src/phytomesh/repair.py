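"""Detection and filling of small scan holes.

Thorns and prickles scatter structured light, so a scanned succulent
surface typically comes back with small punctures where they grew.  Each
puncture is a boundary loop far smaller than the genuine open margins
(leaf outline, pot cut).  Holes are told apart from margins purely by
perimeter, filled with a centroid fan (adequate for small, nearly planar
punctures), and the recovered area is reported so the measurement can be
quoted with and without the repair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import BoundaryLoop, TriangleMesh, boundary_loops, surface_area

__all__ = ["detect_holes", "fill_holes", "area_report", "AreaReport"]


def detect_holes(mesh: TriangleMesh, max_perimeter: float = 50.0) -> list[BoundaryLoop]:
    """Boundary loops with perimeter ≤ ``max_perimeter`` mm, smallest first.

    Larger loops — the leaf margin, a pot cut — are excluded; a closed
    mesh yields an empty list.
    """
    loops = [b for b in boundary_loops(mesh) if b.perimeter <= max_perimeter]
    loops.sort(key=lambda b: b.perimeter)
    return loops


def fill_holes(mesh: TriangleMesh, loops: list[BoundaryLoop]) -> TriangleMesh:
    """Triangulate each loop with a fan from its centroid.

    The centroid is appended as a new vertex; existing vertices and faces
    are left untouched, so the boundary loop count drops by exactly
    ``len(loops)``.  Loops wind along the adjacent faces' orientation, so
    the fan triangles are wound opposite to close the surface
    consistently.  Self-intersecting fans on wildly non-planar loops are
    not detected — the fill targets small thorn punctures.
    """
    if not loops:
        return mesh.copy()
    vertices = [mesh.vertices]
    faces = [mesh.faces]
    next_vid = mesh.n_vertices
    for loop in loops:
        ring = np.asarray(loop.vertices, dtype=np.int64)
        centroid = mesh.vertices[ring].mean(axis=0)
        vertices.append(centroid[None, :])
        fan = np.stack(
            [np.roll(ring, -1), ring, np.full(len(ring), next_vid, dtype=np.int64)],
            axis=1,
        )
        faces.append(fan)
        next_vid += 1
    attrs = {}
    for k, v in mesh.attributes.items():
        v = np.asarray(v)
        pad = np.zeros((len(loops),) + v.shape[1:], dtype=v.dtype)
        attrs[k] = np.concatenate([v, pad])
    return TriangleMesh(np.vstack(vertices), np.vstack(faces), attrs)


@dataclass
class AreaReport:
    area_before: float
    area_after: float

    @property
    def filled_area(self) -> float:
        return self.area_after - self.area_before


def area_report(before: TriangleMesh, after: TriangleMesh) -> AreaReport:
    """Surface area before and after filling; the difference is the patch area."""
    return AreaReport(
        area_before=surface_area(before), area_after=surface_area(after)
    )
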