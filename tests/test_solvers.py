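"""Simplex quadrature, collocation assembly, reference integrals, time stepping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import neuralfield as nf
from neuralfield.geodesics import all_pairs_distances, plane_distance_rows
from neuralfield.solvers import (
    MIDPOINT_RULE,
    VERTEX_RULE,
    collocation_integral_at,
    lagrange_basis,
)

PARAMS = nf.NeuralFieldParams()


class TestSimplexMap:
    def test_corner_convention(self):
        v1, v2, v3 = np.array([0.0, 0, 0]), np.array([2.0, 0, 0]), np.array([0.0, 3, 0])
        np.testing.assert_array_equal(nf.simplex_map_T(v1, v2, v3, 0, 0), v1)
        np.testing.assert_array_equal(nf.simplex_map_T(v1, v2, v3, 0, 1), v2)
        np.testing.assert_array_equal(nf.simplex_map_T(v1, v2, v3, 1, 0), v3)

    def test_centroid(self):
        v1, v2, v3 = np.array([0.0, 0, 0]), np.array([3.0, 0, 0]), np.array([0.0, 3, 0])
        np.testing.assert_allclose(
            nf.simplex_map_T(v1, v2, v3, 1 / 3, 1 / 3), (v1 + v2 + v3) / 3
        )

    def test_outside_simplex_rejected(self):
        v = np.zeros(3)
        with pytest.raises(ValueError):
            nf.simplex_map_T(v, v, v, 0.7, 0.7)


class TestSimplexQuadrature:
    @pytest.mark.parametrize(
        "G, exact",
        [
            (lambda r, s: 1.0, 0.5),
            (lambda r, s: r, 1 / 6),
            (lambda r, s: r + s, 1 / 3),
        ],
    )
    def test_vertex_rule_exact_for_linears(self, G, exact):
        assert nf.integrate_on_simplex(G, VERTEX_RULE) == pytest.approx(exact)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2))
    def test_vertex_rule_exact_for_random_linear(self, a, b, c):
        G = lambda r, s: a + b * r + c * s
        exact = a / 2 + (b + c) / 6
        assert nf.integrate_on_simplex(G, VERTEX_RULE) == pytest.approx(exact, abs=1e-12)

    def test_midpoint_rule_exact_for_quadratics(self):
        # int_sigma r^2 = 1/12, int_sigma r s = 1/24
        assert nf.integrate_on_simplex(lambda r, s: r * r, MIDPOINT_RULE) == pytest.approx(1 / 12)
        assert nf.integrate_on_simplex(lambda r, s: r * s, MIDPOINT_RULE) == pytest.approx(1 / 24)

    def test_weights_must_cover_simplex_area(self):
        with pytest.raises(ValueError):
            nf.SimplexQuadrature("bad", nodes=((0.0, 0.0),), weights=(1.0,))


def _direct_triangle_loop(mesh, u, distance_row, params):
    """Brute-force per-triangle evaluation of the collocation integral.

    Independently sums Area/3 * [w S + w S + w S] over triangles without the
    node-regrouped matrix shortcut.
    """
    rate = nf.firing_rate_S(u - params.h, params.beta)
    w_row = nf.kernel_w(distance_row, params)
    total = 0.0
    for k in range(mesh.n_triangles):
        area = mesh.triangle_areas[k]
        for j in mesh.node_triangles[k]:
            total += area / 3.0 * w_row[j] * rate[j]
    return total


class TestCollocationOperator:
    def test_matches_brute_force_triangle_loop(self):
        mesh = nf.build_irregular_plane_mesh(7.5, 120, seed=4)
        pts = mesh.node_positions
        dm = all_pairs_distances(mesh)
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        rng = np.random.default_rng(0)
        u = rng.normal(0.5, 0.5, mesh.n_nodes)
        rep = 7
        direct = _direct_triangle_loop(mesh, u, dm.values[rep], PARAMS)
        assert op.apply(u)[rep] == pytest.approx(direct, rel=1e-12)
        assert collocation_integral_at(mesh, u, dm.values[rep], PARAMS) == pytest.approx(
            direct, rel=1e-12
        )

    def test_regular_plane_weights_are_trapezoidal(self, plane65):
        """On the regular periodic grid the node weight collapses to dx^2."""
        mesh, dm = plane65
        dx = mesh.structured.spacing[0]
        q = mesh.node_quadrature_weights()
        np.testing.assert_allclose(q, dx * dx, rtol=1e-12)
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        expected = nf.kernel_w(dm.values[3], PARAMS) * dx * dx
        np.testing.assert_allclose(op.matrix[3], expected, rtol=1e-12)

    def test_constant_field_gives_kernel_mass_times_rate(self, plane65):
        mesh, dm = plane65
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        c = 1.3
        out = op.apply(np.full(mesh.n_nodes, c))
        expected = op.row_sums * nf.firing_rate_S(c - PARAMS.h, PARAMS.beta)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_midpoint_rule_operator_close_to_vertex_rule_away_from_peak(self):
        """The two rules differ at coarse-grid peaks but agree in the far field."""
        mesh = nf.build_torus_mesh(nf.TorusDomain(4.5, 2.0), 16, 32)
        dm = all_pairs_distances(mesh)
        u = nf.kernel_w(dm.values[0], PARAMS)
        op1 = nf.assemble_collocation_operator(mesh, dm, PARAMS, rule=VERTEX_RULE)
        op2 = nf.assemble_collocation_operator(mesh, dm, PARAMS, rule=MIDPOINT_RULE)
        a, b = op1.apply(u), op2.apply(u)
        far = dm.values[0] > 3.0
        assert np.max(np.abs(a[far] - b[far])) < 0.05 * np.max(np.abs(a))


class TestPlanarIntegrals:
    def test_collocation_trapezoid_fft_machine_precision(self, plane65):
        mesh, dm = plane65
        u = nf.kernel_w(dm.values[0], PARAMS)
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        colloc = op.apply(u)
        fft = nf.fft_integral_plane(u, mesh, PARAMS)
        sel = np.arange(0, mesh.n_nodes, 61)
        trap = nf.trapezoid_integral_plane(u, mesh, PARAMS, nodes=sel)
        scale = np.max(np.abs(colloc))
        assert np.max(np.abs(colloc - fft)) / scale < 1e-12
        assert np.max(np.abs(colloc[sel] - trap)) / scale < 1e-12

    def test_fft_delta_input_returns_kernel_row(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 17)
        n = mesh.n_nodes
        u = np.full(n, -1e6)  # S -> 0 everywhere
        u[5] = 1e6  # except one saturated node
        out = nf.fft_integral_plane(u, mesh, PARAMS)
        dx2 = mesh.structured.spacing[0] ** 2
        row = nf.kernel_w(
            plane_distance_rows(mesh.node_positions, mesh.node_positions[5:6], 7.5)[0],
            PARAMS,
        )
        np.testing.assert_allclose(out, row * dx2, atol=1e-12)

    def test_non_regular_mesh_rejected(self):
        mesh = nf.build_irregular_plane_mesh(7.5, 100, seed=0)
        with pytest.raises(ValueError):
            nf.trapezoid_integral_plane(np.zeros(mesh.n_nodes), mesh)


class TestTorusTrapezoid:
    def test_constant_kernel_reduces_to_surface_area(self):
        """With d = 0 everywhere and saturated u, the sum is w(0) * 4 pi^2 R r."""
        dom = nf.TorusDomain(4.5, 2.0)
        mesh = nf.build_torus_mesh(dom, 32, 64)
        n = mesh.n_nodes
        out = nf.trapezoid_integral_torus(
            np.full(n, 1e6), mesh, np.zeros((1, n)), PARAMS, nodes=[0]
        )
        assert out[0] == pytest.approx(0.83 * dom.area, rel=1e-12)

    def test_mirror_symmetry_in_phi(self, torus_fine):
        mesh, dm = torus_fine
        nt, nph = mesh.structured.shape
        theta, _ = mesh.domain.angles(mesh.node_positions)
        u = np.cos(theta)  # phi-symmetric field
        i, j = 3, 5
        nodes = [i * nph + j, i * nph + (nph - j)]
        out = nf.trapezoid_integral_torus(u, mesh, dm, PARAMS, nodes=nodes)
        # mirror symmetry is exact up to the diagonal-split asymmetry of the
        # marching backend's distance rows
        assert out[0] == pytest.approx(out[1], rel=2e-2)


class TestTimeIntegration:
    def test_decoupled_recovery_decays_exponentially(self, plane65):
        mesh, dm = plane65
        params = nf.NeuralFieldParams(B=0.0, A=0.0)
        op = nf.assemble_collocation_operator(mesh, dm, params)
        a0 = 1.7
        init = nf.FieldState(u=np.zeros(mesh.n_nodes), a=np.full(mesh.n_nodes, a0))
        series = nf.integrate_time(op, params, init, T=6.0)
        expected = a0 * np.exp(-series.times / params.tau)
        np.testing.assert_allclose(series.a[:, 0], expected, atol=1e-5)

    def test_tolerance_halving_changes_little(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 17)
        dm = all_pairs_distances(mesh)
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        init = nf.make_initial_condition(mesh, nf.PatchSpec.plane_default())
        s1 = nf.integrate_time(op, PARAMS, init, T=30.0, rtol=1e-6, atol=1e-6)
        s2 = nf.integrate_time(op, PARAMS, init, T=30.0, rtol=5e-7, atol=5e-7)
        assert np.max(np.abs(s1.u[-1] - s2.u[-1])) < 1e-4

    def test_dimension_mismatch_rejected(self, plane65):
        mesh, dm = plane65
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        bad = nf.FieldState(u=np.zeros(5), a=np.zeros(5))
        with pytest.raises(ValueError):
            nf.integrate_time(op, PARAMS, bad, T=1.0)


def test_lagrange_basis_partition_of_unity():
    for r, s in [(0.1, 0.2), (0.3, 0.3), (0.0, 0.9)]:
        assert lagrange_basis(r, s).sum() == pytest.approx(1.0)
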