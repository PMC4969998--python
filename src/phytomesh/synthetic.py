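"""Deterministic synthetic meshes with analytically known measurements.

Scanned plant accessions are rarely shareable, so every measurement in
this package is validated on generated surfaces whose ground truth is a
closed form:

* :func:`uv_sphere` — the latitude/longitude sphere used to validate area
  and volume computation (radius 50 mm at 2° angular resolution gives a
  1.7 mm vertex spacing on the equator);
* :func:`twisted_ribbon` — a long narrow leaf twisted about a longitudinal
  axis, emulating a *Welwitschia mirabilis* leaf, the hard case for leaf
  length measurement; with ``helix_radius > 0`` the midline itself is a
  helix of known arc length;
* :func:`perforated_ribbon` — a ribbon with small punched holes, standing
  in for the gaps a scanner leaves where thorns grew;
* :func:`blob` — a closed bumpy sphere for closed-surface studies that
  should not be a perfect sphere;
* :func:`primitive` — exact cube / regular tetrahedron for oracle tests.

All generators are pure functions of their spec (plus an optional integer
seed), so fixtures are reproducible byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh

__all__ = [
    "SphereSpec",
    "RibbonSpec",
    "uv_sphere",
    "twisted_ribbon",
    "perforated_ribbon",
    "blob",
    "primitive",
]


@dataclass(frozen=True)
class SphereSpec:
    """Latitude/longitude sphere.

    ``resolution_deg`` must divide 360 so the longitude circles close;
    latitude rings sit at every multiple of the resolution strictly
    between the poles (when 180 is not an exact multiple — e.g. 8° — the
    band touching the south pole is simply thinner than the rest).
    """

    radius: float = 50.0
    resolution_deg: float = 2.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        lon = 360.0 / self.resolution_deg
        if abs(lon - round(lon)) > 1e-9 or round(lon) < 3 or self.resolution_deg > 90:
            raise ValueError(
                f"angular resolution {self.resolution_deg}° must divide 360° "
                "and be at most 90°"
            )

    @property
    def n_lon(self) -> int:
        return int(round(360.0 / self.resolution_deg))

    @property
    def n_rings(self) -> int:
        # multiples of the resolution strictly inside (0°, 180°)
        return int(np.ceil(180.0 / self.resolution_deg - 1e-9)) - 1

    @property
    def vertex_count(self) -> int:
        return 2 + self.n_rings * self.n_lon

    @property
    def face_count(self) -> int:
        return 2 * self.vertex_count - 4


@dataclass(frozen=True)
class RibbonSpec:
    """A length × width ribbon swept along a straight axis while rotating.

    ``twist_turns`` full rotations are distributed uniformly along the
    length.  With ``helix_radius = 0`` (default) the ribbon twists about
    its own midline, which therefore stays the straight axis of length
    ``length``; with ``helix_radius = d > 0`` the midline traces a helix
    of radius ``d`` whose arc length is ``length·sqrt(1 + (2π·twist·d /
    length)²)`` — a twisted leaf whose true centerline is strictly longer
    than the chord between its ends.
    """

    length: float = 180.0
    width: float = 30.0
    twist_turns: float = 0.0
    n_length: int = 181
    n_width: int = 31
    helix_radius: float = 0.0

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")
        if self.n_length < 2 or self.n_width < 2:
            raise ValueError("need at least 2 samples in each direction")
        if self.helix_radius < 0:
            raise ValueError("helix_radius must be non-negative")

    @property
    def midline_arc_length(self) -> float:
        """Closed-form length of the midline curve."""
        rate = 2.0 * math.pi * self.twist_turns * self.helix_radius / self.length
        return self.length * math.sqrt(1.0 + rate * rate)

    def edge_arc_length(self, width_fraction: float) -> float:
        """Closed-form helix length traced at a given across-width position."""
        t = (width_fraction - 0.5) * self.width
        rho = abs(self.helix_radius + t)
        rate = 2.0 * math.pi * self.twist_turns * rho / self.length
        return self.length * math.sqrt(1.0 + rate * rate)


def _grid_faces(ni: int, nj: int) -> np.ndarray:
    """Triangulated ni × nj grid, diagonal (i,j)–(i+1,j+1), consistent winding."""
    idx = np.arange(ni * nj).reshape(ni, nj)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    return np.concatenate(
        [np.stack([a, d, b], axis=1), np.stack([a, c, d], axis=1)]
    )


def uv_sphere(spec: SphereSpec | None = None, **kw) -> TriangleMesh:
    """Latitude/longitude sphere, closed, manifold and outward-oriented.

    Rings sit at every multiple of the angular resolution between the
    poles; quads between adjacent rings are split along the
    (ring i, lon j)–(ring i+1, lon j+1) diagonal; the poles are capped
    with triangle fans.  Vertices lie exactly on the sphere.
    """
    spec = spec or SphereSpec(**kw)
    r = spec.radius
    n_lon = spec.n_lon
    rings = spec.n_rings
    thetas = np.deg2rad(np.arange(1, rings + 1) * spec.resolution_deg)
    phis = np.deg2rad(np.arange(n_lon) * spec.resolution_deg)
    st, ct = np.sin(thetas), np.cos(thetas)
    cp, sp = np.cos(phis), np.sin(phis)
    ring_pts = np.empty((rings, n_lon, 3))
    ring_pts[:, :, 0] = r * st[:, None] * cp[None, :]
    ring_pts[:, :, 1] = r * st[:, None] * sp[None, :]
    ring_pts[:, :, 2] = r * ct[:, None]
    vertices = np.vstack(
        [[[0.0, 0.0, r]], ring_pts.reshape(-1, 3), [[0.0, 0.0, -r]]]
    )

    def rid(i, j):
        return 1 + i * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):
        faces.append((0, rid(0, j), rid(0, j + 1)))
    for i in range(rings - 1):
        for j in range(n_lon):
            A, B = rid(i, j), rid(i, j + 1)
            C, D = rid(i + 1, j), rid(i + 1, j + 1)
            faces.append((A, D, B))
            faces.append((A, C, D))
    south = len(vertices) - 1
    for j in range(n_lon):
        faces.append((south, rid(rings - 1, j + 1), rid(rings - 1, j)))
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def twisted_ribbon(spec: RibbonSpec | None = None, **kw) -> TriangleMesh:
    """Open ribbon mesh with per-vertex sweep parameters attached.

    The returned mesh carries ``length_fraction`` and ``width_fraction``
    vertex attributes (the sweep parameters), giving tests analytic ground
    truth for "how far along the leaf" and "how far across" each vertex is.
    """
    spec = spec or RibbonSpec(**kw)
    s_frac = np.linspace(0.0, 1.0, spec.n_length)
    t_frac = np.linspace(0.0, 1.0, spec.n_width)
    S, Tf = np.meshgrid(s_frac, t_frac, indexing="ij")
    s = S * spec.length
    t = (Tf - 0.5) * spec.width
    phi = 2.0 * np.pi * spec.twist_turns * S
    rho = spec.helix_radius + t
    x = rho * np.cos(phi)
    y = rho * np.sin(phi)
    z = s
    vertices = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    faces = _grid_faces(spec.n_length, spec.n_width)
    return TriangleMesh(
        vertices,
        faces,
        attributes={
            "length_fraction": S.ravel().copy(),
            "width_fraction": Tf.ravel().copy(),
        },
    )


def perforated_ribbon(
    spec: RibbonSpec,
    holes: list[tuple[float, float, float]],
    seed: int | None = None,
    jitter: float = 0.0,
) -> TriangleMesh:
    """Ribbon with circular holes punched in parameter space.

    Each hole is ``(length_fraction, width_fraction, radius_mm)``; a face
    is removed when all three of its vertices fall inside the hole disc
    measured in the flattened (s·length, t·width) millimetre plane — the
    same thing a thorn does to a scan.  ``seed`` drives an optional
    deterministic jitter of the hole centres (``jitter`` mm standard
    deviation).  Holes must not overlap.
    """
    centers = np.array([(h[0] * spec.length, h[1] * spec.width) for h in holes])
    radii = np.array([h[2] for h in holes], dtype=float)
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.normal(0.0, jitter, size=centers.shape)
    for i in range(len(holes)):
        for j in range(i + 1, len(holes)):
            if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                raise ValueError(f"holes {i} and {j} overlap")
    mesh = twisted_ribbon(spec)
    s_mm = mesh.attributes["length_fraction"] * spec.length
    t_mm = mesh.attributes["width_fraction"] * spec.width
    inside = np.zeros(mesh.n_vertices, dtype=bool)
    for (cs, ct_), r in zip(centers, radii):
        inside |= (s_mm - cs) ** 2 + (t_mm - ct_) ** 2 <= r * r
    drop = inside[mesh.faces].all(axis=1)
    keep_faces = mesh.faces[~drop]
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[keep_faces.ravel()] = True
    remap = np.cumsum(used) - 1
    return TriangleMesh(
        mesh.vertices[used],
        remap[keep_faces],
        attributes={k: v[used] for k, v in mesh.attributes.items()},
    )


def blob(
    radius: float = 50.0,
    resolution_deg: float = 2.0,
    amplitude: float = 0.08,
    seed: int = 0,
) -> TriangleMesh:
    """Closed bumpy sphere: radius modulated by low-order angular harmonics.

    ``amplitude`` is the relative modulation depth.  Deterministic for a
    given seed (the seed selects the harmonic phases), genus 0, and far
    enough from a perfect sphere that closed-surface code paths cannot
    rely on symmetry.
    """
    base = uv_sphere(SphereSpec(radius=radius, resolution_deg=resolution_deg))
    v = base.vertices
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    rng = np.random.default_rng(seed)
    p1, p2, p3 = rng.uniform(0.0, 2.0 * np.pi, size=3)
    mod = (
        0.5 * np.sin(3.0 * theta) * np.cos(2.0 * phi + p1)
        + 0.3 * np.cos(2.0 * theta + p2) * np.sin(3.0 * phi)
        + 0.2 * np.sin(4.0 * theta + p3)
    )
    scale = 1.0 + amplitude * mod
    return TriangleMesh(v * scale[:, None], base.faces.copy())


_CUBE_V = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
_CUBE_F = np.array(
    [
        [0, 2, 1], [0, 3, 2],          # bottom (z=0, outward -z)
        [4, 5, 6], [4, 6, 7],          # top
        [0, 1, 5], [0, 5, 4],          # y=0
        [1, 2, 6], [1, 6, 5],          # x=1
        [2, 3, 7], [2, 7, 6],          # y=1
        [3, 0, 4], [3, 4, 7],          # x=0
    ]
)

# regular tetrahedron with unit edge, outward-oriented
_TET_V = np.array(
    [
        [1, 1, 1],
        [1, -1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
    ],
    dtype=float,
) / np.sqrt(8.0)
_TET_F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


def primitive(name: str, size: float = 1.0) -> TriangleMesh:
    """Exact canonical solids (``cube`` or ``tetrahedron``) with edge ``size``."""
    if name == "cube":
        return TriangleMesh(_CUBE_V * size, _CUBE_F.copy())
    if name == "tetrahedron":
        return TriangleMesh(_TET_V * size, _TET_F.copy())
    raise ValueError(f"unknown primitive {name!r}; expected 'cube' or 'tetrahedron'")
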