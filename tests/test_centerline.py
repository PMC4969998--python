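"""Five-step midline leaf-length estimator."""

import numpy as np
import pytest

import phytomesh as pm
from phytomesh.errors import BandPartitionError, PhytomeshError

from conftest import STRIP_SPEC, strip_vertex

START = strip_vertex(0, 15)      # midpoint of the s=0 short edge
END = strip_vertex(180, 15)      # midpoint of the s=180 short edge


# -------------------------------------------------------------- leaf edge set
def test_leaf_edge_set_whole_boundary(strip):
    edges = pm.leaf_edge_set(strip, START, END, exclusion_radius=0.0)
    loops = pm.boundary_loops(strip)
    assert edges == set(loops[0].vertices)


def test_leaf_edge_set_exclusion_removes_short_edge_neighbourhoods(strip):
    edges = pm.leaf_edge_set(strip, START, END, exclusion_radius=20.0)
    g = pm.build_edge_graph(strip)
    near = pm.dijkstra_field(strip, [START, END], graph=g).values
    assert edges  # nonempty
    assert all(near[v] > 20.0 for v in edges)
    # the long sides far from both ends survive
    assert strip_vertex(90, 0) in edges and strip_vertex(90, 30) in edges
    # the short-edge corners do not
    assert strip_vertex(0, 0) not in edges and strip_vertex(180, 30) not in edges


def test_leaf_edge_set_closed_mesh_is_an_error(sphere30):
    with pytest.raises(PhytomeshError, match="closed"):
        pm.leaf_edge_set(sphere30, 0, 5)


def test_leaf_edge_set_overlarge_exclusion(strip):
    with pytest.raises(PhytomeshError, match="smaller radius"):
        pm.leaf_edge_set(strip, START, END, exclusion_radius=1e6)


# --------------------------------------------------------- edge distance field
def test_edge_distance_field_strip_ridge(strip):
    edges = pm.leaf_edge_set(strip, START, END)
    f = pm.edge_distance_field(strip, edges)
    assert f.provenance == "edge map"
    assert np.allclose(f.values[list(edges)], 0.0)
    # interior maximum sits on the midline at about half the width
    assert f.values.max() == pytest.approx(15.0, rel=0.05)
    ridge = np.flatnonzero(f.values > 0.95 * f.values.max())
    assert np.allclose(strip.attributes["width_fraction"][ridge], 0.5, atol=0.1)


def test_edge_field_maxima_trace_midline_on_twisted_ribbon():
    spec = pm.RibbonSpec(length=120, width=30, twist_turns=1.5,
                         n_length=241, n_width=31)
    rib = pm.twisted_ribbon(spec)
    start, end = strip_vertex(0, 15), strip_vertex(240, 15)
    edges = pm.leaf_edge_set(rib, start, end)
    f = pm.edge_distance_field(rib, edges)
    interior = (rib.attributes["length_fraction"] > 0.2) & (
        rib.attributes["length_fraction"] < 0.8
    )
    ridge = np.flatnonzero(interior & (f.values > 0.9 * f.values[interior].max()))
    assert len(ridge) > 0
    assert np.allclose(rib.attributes["width_fraction"][ridge], 0.5, atol=0.1)


# -------------------------------------------------------------------- banding
def test_band_partition_arithmetic(strip):
    src = pm.fmm_distance(strip, [START])
    bands = pm.band_partition(src, END, k=3)
    s_mm = strip.attributes["length_fraction"] * 180.0
    # band boundaries at 60 and 120 mm of geodesic distance from the start;
    # sample well inside each band (the FMM field is exact on this strip)
    assert bands[strip_vertex(30, 15)] == 0
    assert bands[strip_vertex(90, 15)] == 1
    assert bands[strip_vertex(150, 15)] == 2
    assert bands[END] == 2
    assert set(np.unique(bands)) == {0, 1, 2}
    assert np.all(bands[s_mm < 59] <= 1)


def test_band_partition_k_too_small(strip):
    src = pm.fmm_distance(strip, [START])
    with pytest.raises(ValueError, match="at least 3"):
        pm.band_partition(src, END, k=2)


def test_band_partition_empty_band_is_an_error():
    # synthetic field: everything near the start except the far end point
    values = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
    field = pm.ScalarField(values=values, sources=frozenset({0}))
    with pytest.raises(BandPartitionError, match="band"):
        pm.band_partition(field, end=4, k=5)


def test_band_waypoints_counting_and_ties():
    bands = np.array([0, 0, 1, 1, 1, 2, 2])
    edge_vals = np.array([9.0, 1.0, 5.0, 5.0, 2.0, 1.0, 9.0])
    field = pm.ScalarField(values=edge_vals, sources=frozenset())
    wps = pm.band_waypoints(field, bands, start=0, end=6)
    # bands 0 and 2 hold the endpoints; band 1 ties at vertices 2 and 3
    assert wps == [2]


def test_k3_yields_single_waypoint(strip):
    res = pm.centerline_length(strip, START, END, k=3)
    assert len(res.waypoints) == 1


# ------------------------------------------------------------------ full runs
def test_centerline_straight_strip(strip):
    res = pm.centerline_length(strip, START, END, k=10)
    assert 180.0 <= res.length <= 183.6
    assert len(res.waypoints) == 8
    wf = strip.attributes["width_fraction"][res.waypoints]
    assert np.all((wf >= 0.4) & (wf <= 0.6))
    # the chained path can never beat the direct shortest path
    direct = pm.dijkstra_path(strip, START, END).length
    assert res.length >= direct - 1e-9


def test_centerline_k_robustness_on_strip(strip):
    l3 = pm.centerline_length(strip, START, END, k=3).length
    l10 = pm.centerline_length(strip, START, END, k=10).length
    assert abs(l3 - l10) / l10 < 0.01


def test_centerline_direction_symmetry(strip):
    fwd = pm.centerline_length(strip, START, END, k=10).length
    rev = pm.centerline_length(strip, END, START, k=10).length
    assert abs(fwd - rev) / fwd < 0.01


def test_centerline_refinement_overestimate_non_increasing():
    lengths = []
    for n in (91, 181, 361):  # 2 mm, 1 mm, 0.5 mm resolution
        spec = pm.RibbonSpec(length=180, width=30, twist_turns=0.0,
                             n_length=n, n_width=(n - 1) // 6 + 1)
        rib = pm.twisted_ribbon(spec)
        start = strip_vertex(0, (spec.n_width - 1) // 2, spec.n_width)
        end = strip_vertex(spec.n_length - 1, (spec.n_width - 1) // 2, spec.n_width)
        lengths.append(pm.centerline_length(rib, start, end, k=10).length)
    over = [l - 180.0 for l in lengths]
    assert all(o >= -1e-9 for o in over)
    assert over[0] >= over[1] >= over[2]


def test_centerline_twisted_ribbon_recovers_helical_midline():
    spec = pm.RibbonSpec(length=180, width=30, twist_turns=2.0,
                         n_length=721, n_width=31, helix_radius=35.0)
    rib = pm.twisted_ribbon(spec)
    start, end = strip_vertex(0, 15), strip_vertex(720, 15)
    res = pm.centerline_length(rib, start, end, k=10)
    assert res.length == pytest.approx(spec.midline_arc_length, rel=0.03)
    direct = pm.dijkstra_path(rib, start, end).length
    assert res.length > direct
    wf = rib.attributes["width_fraction"][res.waypoints]
    assert np.all((wf >= 0.4) & (wf <= 0.6))


def test_snap_to_vertex(strip):
    target = strip.vertices[START] + [0.2, -0.1, 0.3]
    assert pm.snap_to_vertex(strip, target) == START
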