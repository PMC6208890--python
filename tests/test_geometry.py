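"""Mesh generators, refinement, curvature and OFF/PLY round trips."""

import numpy as np
import pytest

import neuralfield as nf
from neuralfield.geometry import (
    MeshParseError,
    angle_defects,
    refinement_schedule,
)


class TestCartesianPlane:
    def test_node_and_triangle_counts(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 9)
        assert mesh.n_vertices == 81
        assert mesh.n_triangles == 2 * 8 * 8
        fine = nf.build_cartesian_plane_mesh(7.5, 65)
        assert fine.n_vertices == 4225

    def test_refinement_schedule_matches_grid(self):
        for m in range(4):
            assert refinement_schedule(m) == (2**m * 8 + 1) ** 2

    def test_every_identified_node_has_six_incident_triangles(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 9)
        assert set(mesh.node_incidence_counts().tolist()) == {6}

    def test_quadrisection_reaches_stage_three_count(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 9)
        for _ in range(3):
            mesh = nf.refine_quadrisect(mesh)
        assert mesh.n_vertices == 4225
        assert set(mesh.node_incidence_counts().tolist()) == {6}

    def test_periodic_identification_is_torus_topology(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 9)
        assert mesh.is_closed
        assert mesh.euler_characteristic == 0

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            nf.build_cartesian_plane_mesh(7.5, 1)
        with pytest.raises(ValueError):
            nf.build_cartesian_plane_mesh(-1.0, 9)


class TestIrregularPlane:
    def test_node_count_near_target_and_determinism(self):
        a = nf.build_irregular_plane_mesh(7.5, 79, seed=0)
        b = nf.build_irregular_plane_mesh(7.5, 79, seed=0)
        assert abs(a.n_nodes - 79) <= 0.15 * 79
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.triangles, b.triangles)

    def test_interior_nodes_off_lattice_and_boundary_on_square(self):
        mesh = nf.build_irregular_plane_mesh(7.5, 200, seed=1)
        xy = mesh.vertices[:, :2]
        on_boundary = np.isclose(np.abs(xy), 7.5).any(axis=1)
        assert on_boundary.sum() >= 8
        interior = xy[~on_boundary]
        # no two interior nodes share an x or y coordinate exactly (no lattice)
        assert len(np.unique(interior[:, 0])) == len(interior)

    def test_no_degenerate_triangles(self):
        mesh = nf.build_irregular_plane_mesh(7.5, 150, seed=2)
        assert mesh.triangle_areas.min() > 1e-12 * 15.0**2

    def test_rejects_tiny_targets(self):
        with pytest.raises(ValueError):
            nf.build_irregular_plane_mesh(7.5, 5, seed=0)


class TestTorus:
    def test_eq11_lattice_gives_162_nodes_324_triangles(self):
        mesh = nf.build_torus_mesh(nf.TorusDomain(4.5, 2.0), 9, 18)
        assert mesh.n_vertices == 162
        assert mesh.n_triangles == 324
        assert mesh.is_closed
        assert mesh.euler_characteristic == 0

    def test_refinement_preserves_closedness_and_reprojects(self):
        dom = nf.TorusDomain(4.5, 2.0)
        mesh = nf.refine_quadrisect(nf.build_torus_mesh(dom, 9, 18))
        assert mesh.n_triangles == 4 * 324
        assert mesh.euler_characteristic == 0
        # every vertex lies on the analytic surface after reprojection
        proj = dom.project(mesh.vertices)
        np.testing.assert_allclose(proj, mesh.vertices, atol=1e-12)

    def test_area_converges_to_4pi2Rr_at_order_two(self):
        counts, areas, order = nf.analysis.torus_area_convergence(m_max=4)
        exact = 4 * np.pi**2 * 4.5 * 2.0
        assert abs(areas[-1] - exact) / exact < 2e-4
        assert order == pytest.approx(2.0, abs=0.1)

    def test_rejects_small_lattices(self):
        with pytest.raises(ValueError):
            nf.build_torus_mesh(nf.TorusDomain(4.5, 2.0), 2, 18)


class TestCurvature:
    def test_analytic_torus_values(self):
        dom = nf.TorusDomain(4.5, 2.0)
        assert dom.gaussian_curvature(0.0) == pytest.approx(1 / 13.0)
        assert dom.gaussian_curvature(np.pi) == pytest.approx(-0.2)

    def test_gauss_bonnet_on_torus_and_sphere(self):
        mesh = nf.build_torus_mesh(nf.TorusDomain(4.5, 2.0), 12, 24)
        assert angle_defects(mesh).sum() == pytest.approx(0.0, abs=1e-9)
        trimesh = pytest.importorskip("trimesh")
        ico = trimesh.creation.icosphere(subdivisions=2)
        sphere = nf.TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        assert angle_defects(sphere).sum() == pytest.approx(4 * np.pi, rel=1e-9)

    def test_discrete_matches_analytic_on_fine_torus(self):
        dom = nf.TorusDomain(4.5, 2.0)
        mesh = nf.build_torus_mesh(dom, 32, 64)
        K_disc = nf.gaussian_curvature(mesh)
        K_true = nf.gaussian_curvature(mesh, analytic=True)
        assert np.max(np.abs(K_disc - K_true)) < 0.02

    def test_boundary_mesh_rejected(self):
        # a single-cell open patch has boundary vertices
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        tris = np.array([[0, 1, 3], [0, 3, 2]])
        open_mesh = nf.TriMesh(verts, tris)
        with pytest.raises(ValueError):
            nf.gaussian_curvature(open_mesh)


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_round_trip_preserves_connectivity(self, tmp_path, ext):
        mesh = nf.build_torus_mesh(nf.TorusDomain(4.5, 2.0), 9, 18)
        path = tmp_path / f"torus.{ext}"
        nf.save_mesh(mesh, path)
        back = nf.load_mesh(path)
        np.testing.assert_array_equal(back.triangles, mesh.triangles)
        np.testing.assert_allclose(back.vertices, mesh.vertices, rtol=0, atol=1e-12)
        assert back.is_closed

    def test_off_round_trip_against_trimesh(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        mesh = nf.build_torus_mesh(nf.TorusDomain(4.5, 2.0), 9, 18)
        path = tmp_path / "torus.off"
        nf.save_mesh(mesh, path)
        other = trimesh.load(str(path), process=False)
        np.testing.assert_allclose(np.asarray(other.vertices), mesh.vertices, atol=1e-9)
        np.testing.assert_array_equal(np.asarray(other.faces), mesh.triangles)

    def test_bad_face_row_names_line(self, tmp_path):
        path = tmp_path / "bad.off"
        path.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n5 0 1 2 0 1\n")
        with pytest.raises(MeshParseError, match="line 6"):
            nf.load_mesh(path)

    def test_open_mesh_reports_not_closed(self, tmp_path):
        path = tmp_path / "open.off"
        path.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
        mesh = nf.load_mesh(path)
        assert not mesh.is_closed
        assert len(mesh.boundary_edges) == 3
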