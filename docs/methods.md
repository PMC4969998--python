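# Methods

## Scope and model

`phytomesh` measures morphological parameters of plants from triangle
meshes produced by surface scanning: path lengths constrained to the
surface, blade area, enclosed volume, the surface-to-volume ratio S/V,
and the behaviour of all of these as a function of mesh resolution.
Coordinates are millimetres; no unit conversion is offered, so areas are
mm², volumes mm³ and S/V mm⁻¹.

A mesh is a pair (V, F): vertex positions and triangles over 0-based
indices. An edge is an unordered vertex pair; a mesh is edge-manifold
when no edge borders more than two faces, closed when every edge borders
exactly two. Volume is defined only for closed, manifold surfaces; the
implementation first makes the winding consistent by breadth-first flood
fill across shared edges, then flips globally if the signed volume is
negative, so the caller never has to care about stored orientation.
Zero-area (sliver) faces are kept in the topology — scanners produce
them, and deleting them silently would change the vertex/face counts a
report is keyed on — but they are listed by `validate_mesh` and
contribute nothing to area or volume.

## Geodesics

Two approximations of geodesic distance are deliberately kept separate:

* **Edge-graph Dijkstra.** The mesh becomes a weighted graph (weights =
  Euclidean edge lengths). Path lengths overestimate true geodesics
  because paths are confined to edges; the overestimate shrinks with the
  lattice and is the method error a practitioner accepts in exchange for
  an explicit vertex path. Determinism: equal-cost frontier vertices are
  settled lowest-index-first, and a vertex's parent is the first
  predecessor that achieved its minimal distance.
* **Fast Marching (FMM).** First-order eikonal solver on the triangle
  fan: each update solves for the arrival time of a locally planar unit-
  speed front crossing a triangle from two already-accepted vertices.
  When the angle at the vertex being updated is obtuse, or the planar
  front is non-causal, the update falls back to the one-point edge
  update (virtual unfolding is not implemented). Because every update is
  the minimum of the two-point value and the one-point (graph) value,
  the FMM field can never exceed the Dijkstra field — a property the
  tests assert exactly. On the 50 mm sphere at 2° the maximum relative
  error against the closed-form arc is 0.02%; at 8° it is 0.24%.

## Centerline (leaf length of a twisted leaf)

The midline length estimator runs in five steps: (1) collect boundary
vertices as the leaf margin, optionally excluding a graph-distance
neighbourhood of the start and end so an attachment scar does not count
as margin (default exclusion 0: the whole boundary is margin); (2) FMM
distance-to-margin field — its ridge is the midline; (3) FMM
distance-from-start field, cut into k equal-distance bands between 0 and
the distance at the end point; (4) in every band except the two holding
the start and end, pick the vertex farthest from the margin (ties to the
lowest index); (5) chain Dijkstra paths start → waypoints (in band
order) → end and sum the segment lengths.

Parameter defaults and rationale:

* **k = 10 bands.** Keeps bands several edge lengths wide on a
  decimetre-scale leaf meshed at ~1 mm while sampling the midline densely
  enough that inter-waypoint shortcuts stay under a percent on the test
  shapes. On a straight strip the result is k-insensitive (k = 3 and
  k = 10 agree to well under 1%).
* **Inter-waypoint paths use Dijkstra**, not FMM gradient backtracking:
  the output should be an explicit vertex path on the mesh, and the
  chained path inherits Dijkstra's determinism.
* Band order, not field value, fixes a waypoint's position in the chain.

Accuracy on generated ground truth: a flat 180 × 30 mm strip at 1 mm
resolution returns 180.0 mm exactly (the grid contains the midline); a
ribbon twisted twice about a 35 mm-radius helical axis (analytic midline
475.2 mm) returns 469.0 mm (−1.3%), while the plain shortest path
returns 334.8 mm (−30%) — the failure mode the estimator exists to fix.

## Resolution analysis

The study remeshes one model to a ladder of target mean edge lengths
(the resolution proxy), measures each rung, and reports errors relative
to the densest model as |reference − model| / reference · 100%. The
absolute value matters: a coarse model can overshoot the reference
(volume does, occasionally) and the error is still reported positive.

Coarsening is shortest-edge-first edge collapse with quadric-optimal
vertex placement:

* processing edges shortest-first drives the edge-length distribution
  toward uniformity and makes the mean edge length rise smoothly, so the
  stop rule can hold the output inside target·[0.9, 1.1];
* the surviving vertex minimises the accumulated quadric (area-weighted
  squared distances to the planes the collapsed region carried). The
  minimiser may sit marginally outside the input surface; that freedom
  is what keeps area and volume nearly unbiased. Projecting vertices
  back onto the input surface instead would inscribe every coarse model
  inside the original curvature and push S/V up by ≈ h²/6R² on a sphere
  of radius R at edge length h — measurable already at 8 mm edges;
* collapses that would change topology (link condition), pinch a
  boundary, or flip a surviving face are rejected, so closedness,
  boundary-loop count and genus survive; boundary edges may only
  collapse along the boundary.

A caveat the tests document deliberately: on closed, nearly convex
bodies, S/V *cannot* stay within 1% of the reference once the area error
exceeds 2%. Among closed surfaces of a given volume the sphere minimises
area, so for any shape-faithful coarse model of a sphere-like reference
the relative area deficit is at most ⅔ of the volume deficit, and the
S/V drift is at least a third of the volume deficit; the three numbers
cannot be 2%, ~3%, <1% simultaneously. S/V stability under resolution
changes is a genuine property of thin, slab-like organs (leaves), where
area and volume losses track each other — not of compact bodies. The
acceptance-style test asserting the sphere/blob conjunction therefore
fails by design and records the measured drift.

Also out of reach by construction: reproducing the absolute area/volume
of any particular scanned specimen (no scan ships with the package); the
arithmetic of the error table is validated on printed measurement values
instead.

## Repair

Thorn punctures appear as small boundary loops. Loops are classified as
holes purely by perimeter (default threshold 50 mm — an order of
magnitude above a thorn scar, an order below a leaf outline); each hole
is filled with a fan from the loop centroid, which is exact for planar
holes that are star-shaped about their centroid (a staircase-shaped hole
outline is overcounted by a fraction of a percent) and adequate for the
nearly planar punctures the scanner leaves.
No curvature-aware filling is attempted: large missing regions are a
reconstruction problem, not a measurement repair. Filling never moves
existing vertices, never removes area, and reduces the boundary-loop
count by exactly the number of filled loops, so volume becomes defined
precisely when every loop has been closed.

## Synthetic ground truth

The generators encode the study conditions rather than convenient test
sizes:

* **uv_sphere** — radius 50 mm, 2° angular steps (16,022 vertices,
  32,040 faces, 1.745 mm equatorial spacing); quads split along the
  (ring i, lon j)–(ring i+1, lon j+1) diagonal, poles capped with fans;
  vertices exactly on the sphere, so inscribed-polyhedron monotonicity
  is exact. The resolution must divide 360° so longitude circles close;
  when it does not divide 180° (the 8° rung of the convergence ladder)
  the band touching the south pole is simply thinner.
* **twisted_ribbon** — 180 × 30 mm default blade, sampled at 1 mm. Twist
  is about the midline by default, making the true centerline length
  exactly the nominal length; `helix_radius = d` moves the twist axis so
  the midline becomes a helix of closed-form length
  L·√(1 + (2π·turns·d/L)²), the configuration in which the centerline
  must strictly exceed the shortest path. Per-vertex sweep parameters
  (length and width fractions) ride along as attributes, giving tests an
  oracle for "how far along/across the leaf" every vertex is.
* **perforated_ribbon** — removes faces whose three corners fall inside
  parameter-space discs; hole discs must not overlap, and realised holes
  each add one boundary loop. Holes should be ≥ ~4 mesh cells across,
  otherwise the staircase hole is materially smaller than the disc.
* **blob** — sphere with low-order harmonic radial modulation (8%
  default), for closed-surface code paths that must not rely on
  spherical symmetry.

What the generators do *not* emulate: scanner noise, registration
artefacts between partial scans, non-uniform sampling density, and
self-contact of heavily curled leaves. Passing tests demonstrate the
measurement layer is correct on clean geometry at scan-like resolution;
they say nothing about segmentation or acquisition quality.

## Numerical choices

* All distances in 64-bit floats, no grid snapping; report rounding
  (integers for measurements, 2 d.p. for percentages) happens only at
  serialisation.
* STL corners are welded by exact bitwise coordinate equality on load;
  PLY/OBJ connectivity is never altered implicitly.
* Degenerate inputs fail loudly: empty meshes, zero-length edges
  (unwelded duplicates), non-manifold edges, unreachable destinations
  and empty centerline bands each raise a typed error.
* Problem sizes used by the test suite — 2° spheres (16k vertices) for
  validation and geodesics, a 1° sphere (64k vertices) coarsened to 1 mm
  for the resolution claim, 721 × 31 ribbons for the twisted-leaf case —
  were chosen as the smallest sizes at which the analytic tolerances are
  meaningful.

## Known limitations

* FMM uses the one-point fallback at obtuse angles instead of virtual
  unfolding; on very obtuse triangulations the field degrades toward the
  graph metric (still never above it).
* Centroid-fan filling can self-intersect on strongly non-planar loops;
  no check is performed.
* The coarsener is coarsening-only; the study never upsamples, and the
  reference is always the input mesh.
* Exact polyhedral geodesics (MMP-style) and the projection-of-a-segment
  distance measurement are out of scope.
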