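"""Kernel, firing rate, kernel mass, initial conditions and uniform states."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import neuralfield as nf
from neuralfield.model import kernel_zero_crossing, reference_node_near_origin

PARAMS = nf.NeuralFieldParams()


class TestKernel:
    def test_value_at_zero_is_083(self):
        assert nf.kernel_w(0.0) == pytest.approx(0.83)

    def test_gaussian_decay_to_zero(self):
        assert abs(nf.kernel_w(10.0)) < 1e-6

    def test_zero_crossing_matches_root_find(self):
        root = brentq(lambda d: nf.kernel_w(d), 1.0, 2.0)
        assert kernel_zero_crossing() == pytest.approx(root, abs=1e-10)
        assert kernel_zero_crossing() == pytest.approx(1.4883, abs=1e-4)

    def test_mexican_hat_sign_structure(self):
        dstar = kernel_zero_crossing()
        d = np.linspace(0, 5, 200)
        w = nf.kernel_w(d)
        assert np.all(w[d < dstar - 1e-9] > 0)
        assert np.all(w[d > dstar + 1e-9] < 0)

    def test_rejects_negative_distances(self):
        with pytest.raises(ValueError):
            nf.kernel_w(-0.1)

    @given(st.floats(0, 20))
    def test_even_in_d_via_squared_argument(self, d):
        # w depends on d only through d^2, so w(d) == exp-combination exactly
        expected = np.exp(-d * d) - 0.17 * np.exp(-0.2 * d * d)
        assert nf.kernel_w(d) == pytest.approx(expected, rel=1e-12)


class TestFiringRate:
    def test_midpoint_and_direct_value(self):
        assert nf.firing_rate_S(0.0) == pytest.approx(0.5)
        assert nf.firing_rate_S(0.2, beta=5.0) == pytest.approx(1 / (1 + np.exp(-1)), rel=1e-12)

    def test_saturation_without_overflow(self):
        assert nf.firing_rate_S(1000.0) == 1.0
        assert nf.firing_rate_S(-1000.0) == 0.0

    @given(st.floats(-6, 6), st.floats(-6, 6))
    def test_strictly_increasing(self, u1, u2):
        # restricted to the range where the sigmoid is resolvable in floats
        if abs(u1 - u2) < 1e-12:
            return
        lo, hi = sorted((u1, u2))
        assert nf.firing_rate_S(lo) < nf.firing_rate_S(hi)

    @given(st.floats(-30, 30))
    def test_odd_symmetry_about_half(self, u):
        assert nf.firing_rate_S(-u) == pytest.approx(1 - nf.firing_rate_S(u), abs=1e-12)

    def test_beta_infinity_approaches_heaviside(self):
        assert nf.firing_rate_S(0.1, beta=500.0) > 0.999
        assert nf.firing_rate_S(-0.1, beta=500.0) < 0.001


class TestKernelMass:
    def test_infinite_plane_closed_form(self):
        # integral of w over R^2: pi - 0.17 pi / 0.2 = 0.15 pi
        big = nf.kernel_mass(nf.PlaneDomain(30.0), grid=1024)
        assert big == pytest.approx(0.15 * np.pi, abs=1e-6)

    def test_periodic_plane_at_L_7_5(self):
        wbar = nf.kernel_mass(nf.PlaneDomain(7.5), grid=512)
        assert wbar == pytest.approx(0.15 * np.pi, abs=1e-4)

    def test_translation_invariance_on_regular_mesh(self, plane65):
        mesh, dm = plane65
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        sums = op.row_sums
        assert np.ptp(sums) < 1e-12
        assert sums[0] == pytest.approx(0.15 * np.pi, abs=1e-3)


class TestInitialConditions:
    def test_plane_defaults_levels(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 33)
        state = nf.make_initial_condition(mesh, nf.PatchSpec.plane_default())
        assert set(np.unique(state.u)) == {0.0, 1.0}
        assert set(np.unique(state.a)) == {0.0, 1.5}
        # a-patch offset in +x relative to u-patch
        x = mesh.node_positions[:, 0]
        assert x[state.a > 0].mean() > x[state.u > 0].mean()

    def test_torus_defaults_levels(self):
        dom = nf.TorusDomain(4.5, 2.0)
        mesh = nf.build_torus_mesh(dom, 24, 48)
        state = nf.make_initial_condition(mesh, nf.PatchSpec.torus_default(dom))
        assert set(np.unique(state.u)) == {0.0, 2.0}
        assert set(np.unique(state.a)) == {0.0, 1.5}

    def test_node_patch_covers_one_percent(self, bumpy_torus):
        mesh, dm = bumpy_torus
        spec = nf.PatchSpec.nodes_default(u_node=0, a_node=5, fraction=0.01)
        state = nf.make_initial_condition(mesh, spec, distances=dm)
        expected = round(0.01 * mesh.n_nodes)
        assert (state.u > 0).sum() == expected
        assert (state.a > 0).sum() == expected

    def test_empty_patch_rejected(self):
        mesh = nf.build_cartesian_plane_mesh(7.5, 9)
        tiny = nf.PatchSpec(kind="plane", u_center=(0.4, 0.4), u_extent=(0.1, 0.1))
        with pytest.raises(ValueError, match="empty"):
            nf.make_initial_condition(mesh, tiny)


class TestUniformFixedPoint:
    def test_recovery_locks_to_Bu(self):
        wbar = nf.kernel_mass(nf.PlaneDomain(7.5))
        u, a = nf.uniform_fixed_point(PARAMS, wbar)
        assert a == pytest.approx(PARAMS.B * u, rel=1e-12)
        lhs = (1 + PARAMS.B) * u
        rhs = PARAMS.A * wbar * nf.firing_rate_S(u - PARAMS.h, PARAMS.beta)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_stationary_under_time_integration(self, plane65):
        mesh, dm = plane65
        op = nf.assemble_collocation_operator(mesh, dm, PARAMS)
        wbar = float(op.row_sums[0])
        u, a = nf.uniform_fixed_point(PARAMS, wbar)
        init = nf.FieldState(u=np.full(mesh.n_nodes, u), a=np.full(mesh.n_nodes, a))
        series = nf.integrate_time(op, PARAMS, init, T=25.0)
        assert np.max(np.abs(series.u[-1] - u)) < 1e-6
        assert np.max(np.abs(series.a[-1] - a)) < 1e-6


def test_params_validation():
    with pytest.raises(ValueError):
        nf.NeuralFieldParams(tau=0.0)
    with pytest.raises(ValueError):
        nf.NeuralFieldParams(beta=-1.0)


def test_reference_node_is_origin_on_regular_grid():
    mesh = nf.build_cartesian_plane_mesh(7.5, 33)
    rep = reference_node_near_origin(mesh)
    np.testing.assert_allclose(mesh.node_positions[rep], [0, 0, 0], atol=1e-12)
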