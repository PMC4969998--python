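"""Mesh data model, I/O and whole-mesh morphometrics."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import phytomesh as pm
from phytomesh.errors import (
    EmptyMeshError,
    MeshParseError,
    NonManifoldError,
    OpenMeshError,
)
from phytomesh.mesh import _signed_volume


# ----------------------------------------------------------------------- I/O
@pytest.mark.parametrize(
    "fmt,ascii_",
    [("ply", True), ("ply", False), ("obj", True), ("stl", True), ("stl", False)],
)
def test_roundtrip_preserves_connectivity_and_coordinates(tmp_path, cube, fmt, ascii_):
    path = tmp_path / f"cube.{fmt}"
    pm.save_mesh(cube, path, ascii=ascii_)
    back = pm.load_mesh(path)
    assert back.n_vertices == 8 and back.n_faces == 12
    if fmt == "stl":
        # STL is a triangle soup: welding recovers the 8 corners but the
        # numbering may differ — compare the vertex sets and face count
        a = np.array(sorted(map(tuple, np.round(back.vertices, 5))))
        b = np.array(sorted(map(tuple, cube.vertices)))
        assert np.allclose(a, b, atol=1e-5)
    else:
        assert np.allclose(back.vertices, cube.vertices, atol=1e-6)
        assert (back.faces == cube.faces).all()


def test_sphere_obj_roundtrip_coordinates(tmp_path, sphere30):
    path = tmp_path / "s.obj"
    pm.save_mesh(sphere30, path)
    back = pm.load_mesh(path)
    assert np.abs(back.vertices - sphere30.vertices).max() < 1e-6
    assert (back.faces == sphere30.faces).all()


def test_stl_welds_duplicate_corners(tmp_path, cube):
    path = tmp_path / "cube.stl"
    pm.save_mesh(cube, path)
    raw = trimesh.load(str(path), process=False)
    assert len(raw.vertices) == 36  # 12 faces x 3 unwelded corners on disk
    welded = pm.load_mesh(path)
    assert welded.n_vertices == 8 and welded.n_faces == 12


def test_obj_one_based_indices_are_converted(tmp_path):
    path = tmp_path / "tri.obj"
    path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
    mesh = pm.load_mesh(path)
    assert mesh.faces.tolist() == [[0, 1, 2]]
    assert pm.surface_area(mesh) == pytest.approx(0.5)


def test_load_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        pm.load_mesh(tmp_path / "missing.ply")
    bad = tmp_path / "bad.ply"
    bad.write_text("this is not a mesh\n")
    with pytest.raises(MeshParseError):
        pm.load_mesh(bad)
    empty = tmp_path / "empty.ply"
    empty.write_text(
        "ply\nformat ascii 1.0\nelement vertex 0\n"
        "property float x\nproperty float y\nproperty float z\n"
        "element face 0\nproperty list uchar int vertex_indices\nend_header\n"
    )
    with pytest.raises(EmptyMeshError):
        pm.load_mesh(empty)


def test_save_empty_mesh_is_an_error(tmp_path):
    empty = pm.TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(EmptyMeshError):
        pm.save_mesh(empty, tmp_path / "x.ply")


def test_degenerate_topological_face_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        pm.TriangleMesh(np.eye(3), [[0, 1, 1]])


# ---------------------------------------------------------------- validation
def test_validate_cube(cube):
    rep = pm.validate_mesh(cube)
    assert rep.is_closed and rep.is_manifold and rep.is_consistently_oriented
    assert rep.boundary_edge_count == 0
    assert rep.euler_characteristic == 2
    assert rep.n_faces == 2 * rep.n_vertices - 4
    assert rep.connected_component_count == 1


def test_validate_cube_missing_face(cube):
    open_cube = pm.TriangleMesh(cube.vertices, cube.faces[:-1])
    rep = pm.validate_mesh(open_cube)
    assert not rep.is_closed
    assert rep.boundary_edge_count == 3


def test_validate_flags_zero_area_faces():
    # a square plus a sliver of three collinear vertices
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [2, 0, 0]], float)
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 1, 4]])  # last face is collinear
    rep = pm.validate_mesh(pm.TriangleMesh(v, f))
    assert rep.degenerate_face_indices == [2]
    # degenerate faces contribute nothing to the area
    assert pm.surface_area(pm.TriangleMesh(v, f)) == pytest.approx(1.0)


# ------------------------------------------------------------- morphometrics
def test_single_triangle_area():
    mesh = pm.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    assert pm.surface_area(mesh) == pytest.approx(0.5)


def test_cube_morphometrics(cube):
    assert pm.surface_area(cube) == pytest.approx(6.0)
    assert pm.enclosed_volume(cube) == pytest.approx(1.0)
    assert pm.sv_ratio(cube) == pytest.approx(6.0)
    assert pm.mean_edge_length(cube) == pytest.approx((12 + 6 * np.sqrt(2)) / 18)


def test_volume_translation_invariance(cube):
    moved = pm.TriangleMesh(cube.vertices + [1000.0, -500.0, 3.0], cube.faces)
    assert pm.enclosed_volume(moved) == pytest.approx(1.0, rel=1e-9)


def test_flipped_winding_same_volume_negated_signed(cube):
    flipped = pm.TriangleMesh(cube.vertices, cube.faces[:, ::-1])
    assert pm.enclosed_volume(flipped) == pytest.approx(1.0, rel=1e-12)
    assert _signed_volume(flipped) == pytest.approx(-_signed_volume(cube))


def test_volume_on_open_mesh_names_loop_count(cube):
    open_cube = pm.TriangleMesh(cube.vertices, cube.faces[:-1])
    with pytest.raises(OpenMeshError, match="1 boundary loop"):
        pm.enclosed_volume(open_cube)
    with pytest.raises(OpenMeshError):
        pm.sv_ratio(open_cube)


def test_scrambled_face_orientation_is_repaired(sphere30):
    rng = np.random.default_rng(7)
    faces = sphere30.faces.copy()
    flip = rng.random(len(faces)) < 0.5
    faces[flip] = faces[flip][:, ::-1]
    scrambled = pm.TriangleMesh(sphere30.vertices, faces)
    assert not pm.validate_mesh(scrambled).is_consistently_oriented
    assert pm.enclosed_volume(scrambled) == pytest.approx(
        pm.enclosed_volume(sphere30), rel=1e-12
    )


def test_mean_edge_equilateral_triangle():
    v = np.array([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]])
    assert pm.mean_edge_length(pm.TriangleMesh(v, [[0, 1, 2]])) == pytest.approx(2.0)


def test_sphere_measurements_match_trimesh_oracle(sphere8):
    blobby = pm.blob(radius=50.0, resolution_deg=8.0, amplitude=0.08, seed=3)
    tm = trimesh.Trimesh(blobby.vertices, blobby.faces, process=False)
    assert pm.surface_area(blobby) == pytest.approx(tm.area, rel=1e-12)
    assert pm.enclosed_volume(blobby) == pytest.approx(abs(tm.volume), rel=1e-12)
    tm2 = trimesh.Trimesh(sphere8.vertices, sphere8.faces, process=False)
    assert pm.surface_area(sphere8) == pytest.approx(tm2.area, rel=1e-12)


def test_sv_ratio_sphere_near_printed_quotient(sphere2):
    # 31,408 / 523,329 of the validation experiment
    assert pm.sv_ratio(sphere2) == pytest.approx(31408 / 523329, rel=2e-4)
    # analytic limit 3/r
    assert pm.sv_ratio(sphere2) == pytest.approx(0.06, rel=2e-3)


# -------------------------------------------------------------- boundary loops
def test_boundary_loops_closed_and_open(sphere30, strip):
    assert pm.boundary_loops(sphere30) == []
    loops = pm.boundary_loops(strip)
    assert len(loops) == 1
    assert loops[0].perimeter == pytest.approx(2 * (180 + 30))


def test_boundary_loops_perforated_strip():
    from tests_support import punched_strip

    mesh = punched_strip(n_holes=3)
    loops = pm.boundary_loops(mesh)
    assert len(loops) == 4


def test_boundary_loops_nonmanifold_edge_rejected():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]], float)
    f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) in three faces
    with pytest.raises(NonManifoldError):
        pm.boundary_loops(pm.TriangleMesh(v, f))


def test_measure_report_serialisation(cube, strip):
    rep = pm.measure(cube)
    assert rep.volume == pytest.approx(1.0)
    assert rep.sv_ratio == pytest.approx(6.0)
    assert '"area"' in rep.to_json()
    assert rep.to_csv_row().splitlines()[0].startswith("vertices,")
    open_rep = pm.measure(strip)
    assert open_rep.volume is None and open_rep.sv_ratio is None
    assert open_rep.area == pytest.approx(180 * 30)


# ----------------------------------------------------------------- properties
@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_rigid_motion_invariance(seed):
    """Area, volume, S/V and mean edge length are rigid-motion invariants."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(seed % 2**16)).as_matrix()
    shift = rng.uniform(-1000, 1000, 3)
    base = pm.primitive("tetrahedron", 2.0)
    moved = pm.TriangleMesh(base.vertices @ rot.T + shift, base.faces)
    assert pm.surface_area(moved) == pytest.approx(pm.surface_area(base), rel=1e-9)
    assert pm.enclosed_volume(moved) == pytest.approx(
        pm.enclosed_volume(base), rel=1e-9
    )
    assert pm.mean_edge_length(moved) == pytest.approx(
        pm.mean_edge_length(base), rel=1e-9
    )


def test_inscribed_polyhedron_bound_and_convergence():
    """Inscribed triangulations underestimate both area and volume, and the
    estimates increase monotonically as the angular resolution refines."""
    analytic_area = 4 * np.pi * 50.0**2
    analytic_vol = 4.0 / 3.0 * np.pi * 50.0**3
    areas, vols = [], []
    for res in (8.0, 4.0, 2.0):
        s = pm.uv_sphere(pm.SphereSpec(50.0, res))
        areas.append(pm.surface_area(s))
        vols.append(pm.enclosed_volume(s))
    assert all(a < analytic_area for a in areas)
    assert all(v < analytic_vol for v in vols)
    assert areas[0] < areas[1] < areas[2]
    assert vols[0] < vols[1] < vols[2]


def test_euler_formula_on_closed_synthetic_meshes(cube, sphere4):
    for mesh in (cube, sphere4, pm.blob(50, 8, 0.08, seed=1)):
        rep = pm.validate_mesh(mesh)
        assert rep.is_closed
        assert rep.n_faces == 2 * rep.n_vertices - 4
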