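"""Spatial discretisation (collocation + reference quadratures) and time stepping.

Piecewise-linear collocation enforces the field equation at the mesh nodes and
approximates the nonlocal integral triangle-by-triangle: the affine map
``T_k(r, s) = (1 - r - s) v1 + s v2 + r v3`` pulls each triangle back to the
unit simplex (Jacobian ``2 Area``), where a simplex quadrature rule is
applied.  With the three-point vertex rule the whole integral collapses to a
dense node-to-node weight matrix acting on ``S(u - h)``; on a regular
periodic Cartesian grid that matrix reproduces the composite trapezoidal rule
exactly, which is why collocation inherits the trapezoidal rule's geometric
(spectral) convergence there.

Reference schemes for comparison: the composite trapezoidal rule on periodic
Cartesian grids, its FFT/circular-convolution equivalent, and the polar-form
trapezoidal rule on regular torus grids (which is not a convolution, so no
FFT shortcut exists there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PlaneDomain, TorusDomain, TriMesh
from .model import FieldState, NeuralFieldParams, firing_rate_S, kernel_w


# ---------------------------------------------------------------------------
# simplex quadrature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimplexQuadrature:
    """Quadrature rule on the unit simplex sigma = {(r, s): r, s >= 0, r + s <= 1}."""

    name: str
    nodes: tuple  # ((r, s), ...)
    weights: tuple

    def __post_init__(self):
        if abs(sum(self.weights) - 0.5) > 1e-14:
            raise ValueError("simplex quadrature weights must sum to 1/2 (area of sigma)")
        for r, s in self.nodes:
            if r < 0 or s < 0 or r + s > 1 + 1e-14:
                raise ValueError("quadrature node outside the unit simplex")


#: three-point vertex rule: int_sigma G = (1/6) [G(0,0) + G(0,1) + G(1,0)];
#: exact for polynomials of total degree <= 1.
VERTEX_RULE = SimplexQuadrature(
    "vertex", nodes=((0.0, 0.0), (0.0, 1.0), (1.0, 0.0)), weights=(1 / 6, 1 / 6, 1 / 6)
)

#: three-point edge-midpoint rule, exact for degree <= 2 (experimental for the
#: collocation operator: kernel values at non-vertex points are obtained from
#: barycentrically interpolated distances).
MIDPOINT_RULE = SimplexQuadrature(
    "midpoint", nodes=((0.0, 0.5), (0.5, 0.0), (0.5, 0.5)), weights=(1 / 6, 1 / 6, 1 / 6)
)


def simplex_map_T(v1, v2, v3, r, s):
    """Affine map from the unit simplex onto the triangle (v1, v2, v3).

    Convention: T(0,0) = v1, T(0,1) = v2, T(1,0) = v3 (s multiplies v2 and
    r multiplies v3).
    """
    if r < -1e-14 or s < -1e-14 or r + s > 1 + 1e-14:
        raise ValueError("(r, s) outside the unit simplex")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    v3 = np.asarray(v3, dtype=float)
    return (1.0 - r - s) * v1 + s * v2 + r * v3


def integrate_on_simplex(G, rule: SimplexQuadrature = VERTEX_RULE) -> float:
    """Apply a simplex quadrature rule to G(r, s)."""
    return float(sum(w * G(r, s) for (r, s), w in zip(rule.nodes, rule.weights)))


def lagrange_basis(r, s):
    """Linear Lagrange basis on the simplex in the (v1, v2, v3) convention."""
    return np.array([1.0 - r - s, s, r])


# ---------------------------------------------------------------------------
# discrete nonlocal operator
# ---------------------------------------------------------------------------

class DiscreteOperator:
    """Discretised nonlocal interaction: I_i ~ sum_j W_ij S(u_j - h).

    For the vertex rule the weights are ``W_ij = w(d_ij) * q_j`` with
    ``q_j = (1/3) sum of incident triangle areas`` (the per-triangle sums of
    the collocation quadrature regrouped node-by-node); ``apply`` then maps
    the firing-rate vector to the integral term (before the gain A).  Row sums
    approximate the kernel mass at each node and are all equal on the regular
    periodic plane (translation invariance).

    Higher-order rules keep the same interface but evaluate the kernel at
    interior quadrature points via barycentric distance interpolation and the
    firing rate of the interpolated field; they act nonlinearly on u.
    """

    def __init__(self, mesh, params, rule, matrix=None, distances=None):
        self.mesh = mesh
        self.params = params
        self.rule = rule
        self.matrix = matrix
        self._distances = distances

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def row_sums(self) -> np.ndarray:
        """Quadrature approximation of the kernel mass at each node."""
        if self.matrix is not None:
            return self.matrix.sum(axis=1)
        # saturate the firing rate so the apply returns the pure kernel quadrature
        return self._apply_nonlinear(np.full(self.n_nodes, 1e6))

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Integral term (before the factor A) for nodal activity u."""
        u = np.asarray(u, dtype=float)
        if u.shape != (self.n_nodes,):
            raise ValueError("field length does not match the operator")
        if self.matrix is not None:
            return self.matrix @ firing_rate_S(u - self.params.h, self.params.beta)
        return self._apply_nonlinear(u)

    def _apply_nonlinear(self, u: np.ndarray) -> np.ndarray:
        D = self._distances
        tris = self.mesh.node_triangles
        areas = self.mesh.triangle_areas
        p = self.params
        out = np.zeros(self.n_nodes)
        for (r, s), wq in zip(self.rule.nodes, self.rule.weights):
            l = lagrange_basis(r, s)
            d_interp = D[:, tris[:, 0]] * l[0] + D[:, tris[:, 1]] * l[1] + D[:, tris[:, 2]] * l[2]
            u_interp = u[tris[:, 0]] * l[0] + u[tris[:, 1]] * l[1] + u[tris[:, 2]] * l[2]
            rate = firing_rate_S(u_interp - p.h, p.beta)
            out += (kernel_w(d_interp, p) * rate) @ (2.0 * areas * wq)
        return out


def assemble_collocation_operator(
    mesh: TriMesh,
    distances,
    params: NeuralFieldParams | None = None,
    rule: SimplexQuadrature = VERTEX_RULE,
) -> DiscreteOperator:
    """Build the dense nonlocal interaction operator for a mesh.

    ``distances`` is a :class:`~neuralfield.geodesics.DistanceMatrix` or a
    plain (n_nodes, n_nodes) array.  No kernel truncation is applied: the
    operator is dense, with an explicit size guard at assembly.
    """
    params = params or NeuralFieldParams()
    D = distances.values if hasattr(distances, "values") else np.asarray(distances)
    n = mesh.n_nodes
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} does not match {n} nodes")
    if n * n * 8 > 4 * 1024**3:
        raise MemoryError("dense operator would exceed the 4 GiB assembly guard")
    if rule.name == "vertex":
        q = mesh.node_quadrature_weights()
        matrix = kernel_w(D, params) * q[None, :]
        return DiscreteOperator(mesh, params, rule, matrix=matrix)
    return DiscreteOperator(mesh, params, rule, distances=D)


def collocation_integral_at(
    mesh: TriMesh, u: np.ndarray, distance_row: np.ndarray, params: NeuralFieldParams | None = None
) -> float:
    """Vertex-rule collocation integral at a single node (O(n) evaluation)."""
    params = params or NeuralFieldParams()
    q = mesh.node_quadrature_weights()
    return float(
        np.sum(q * kernel_w(np.asarray(distance_row), params)
               * firing_rate_S(np.asarray(u) - params.h, params.beta))
    )


# ---------------------------------------------------------------------------
# reference quadratures on structured grids
# ---------------------------------------------------------------------------

def _plane_grid_shape(mesh: TriMesh):
    if mesh.structured is None or not isinstance(mesh.domain, PlaneDomain):
        raise ValueError("this integral requires a regular periodic Cartesian grid mesh")
    return mesh.structured.shape


def trapezoid_integral_plane(
    u: np.ndarray,
    mesh: TriMesh,
    params: NeuralFieldParams | None = None,
    nodes=None,
) -> np.ndarray:
    """Composite trapezoidal rule for the planar nonlocal integral.

    On the 2L-periodic grid every distinct node carries the uniform weight
    ``dx^2``; the kernel uses the analytic minimal-image metric.  ``nodes``
    restricts evaluation to selected node indices (O(n) per node); the default
    evaluates at every node (O(n^2), guarded).
    """
    params = params or NeuralFieldParams()
    g1, g2 = _plane_grid_shape(mesh)
    n = mesh.n_nodes
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError("u must be given per distinct grid node")
    dx = mesh.structured.spacing[0]
    rate = firing_rate_S(u - params.h, params.beta)
    pts = mesh.node_positions
    L = mesh.domain.half_width
    from .geodesics import plane_distance_rows

    if nodes is None:
        if n > 5000:
            raise MemoryError("full trapezoidal evaluation is O(n^2); pass nodes= or use FFT")
        nodes = np.arange(n)
    nodes = np.atleast_1d(np.asarray(nodes, dtype=int))
    rows = plane_distance_rows(pts, pts[nodes], L)
    return (kernel_w(rows, params) @ rate) * dx * dx


def fft_integral_plane(
    u: np.ndarray, mesh: TriMesh, params: NeuralFieldParams | None = None
) -> np.ndarray:
    """Nonlocal planar integral via the convolution theorem (circular FFT).

    Agrees with :func:`trapezoid_integral_plane` to machine precision: both
    are the same periodic Riemann sum, evaluated either directly or in
    Fourier space.
    """
    params = params or NeuralFieldParams()
    g1, g2 = _plane_grid_shape(mesh)
    n = mesh.n_nodes
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError("u must be given per distinct grid node")
    dx = mesh.structured.spacing[0]
    L = mesh.domain.half_width
    from .geodesics import plane_distance_rows

    # kernel sampled around the first grid node; grid ordering is row-major in
    # (x, y) so index displacement equals coordinate displacement mod period
    pts = mesh.node_positions
    krow = kernel_w(plane_distance_rows(pts, pts[:1], L)[0], params).reshape(g1, g2)
    rate = firing_rate_S(u - params.h, params.beta).reshape(g1, g2)
    conv = np.fft.irfft2(np.fft.rfft2(krow) * np.fft.rfft2(rate), s=(g1, g2))
    return conv.ravel() * dx * dx


def trapezoid_integral_torus(
    u: np.ndarray,
    mesh: TriMesh,
    distances,
    params: NeuralFieldParams | None = None,
    nodes=None,
) -> np.ndarray:
    """Polar-form trapezoidal rule on a regular (theta, phi) torus grid.

    Includes the exact area element ``r (R + r cos(theta'))``; the integrand
    is not a convolution on the curved surface, so there is no FFT shortcut.
    """
    params = params or NeuralFieldParams()
    if mesh.structured is None or not isinstance(mesh.domain, TorusDomain):
        raise ValueError("torus trapezoidal rule requires a regular torus grid mesh")
    dom = mesh.domain
    n_theta, n_phi = mesh.structured.shape
    n = mesh.n_nodes
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError("u must be given per grid node")
    D = distances.values if hasattr(distances, "values") else np.asarray(distances)
    dtheta, dphi = mesh.structured.spacing
    theta = np.repeat(mesh.structured.coords1, n_phi)
    element = dom.minor_radius * (dom.major_radius + dom.minor_radius * np.cos(theta))
    weighted = firing_rate_S(u - params.h, params.beta) * element * dtheta * dphi
    if nodes is None:
        if D.shape != (n, n):
            raise ValueError("full evaluation needs the all-pairs distance matrix")
        return kernel_w(D, params) @ weighted
    nodes = np.atleast_1d(np.asarray(nodes, dtype=int))
    rows = D[nodes] if D.ndim == 2 else np.atleast_2d(D)
    return kernel_w(rows, params) @ weighted


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

@dataclass
class FieldSeries:
    """Sampled trajectory of the discretised field."""

    times: np.ndarray
    u: np.ndarray  # (n_times, n_nodes)
    a: np.ndarray

    def __len__(self):
        return len(self.times)

    def state(self, k: int) -> FieldState:
        return FieldState(u=self.u[k], a=self.a[k], t=float(self.times[k]))


def integrate_time(
    operator: DiscreteOperator,
    params: NeuralFieldParams,
    init: FieldState,
    T: float,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    output_stride: float = 1.0,
) -> FieldSeries:
    """Integrate the collocated ODE system with adaptive Runge-Kutta 4(5).

        du_i/dt = -u_i - a_i + A (operator . S(u - h))_i
        da_i/dt = (B u_i - a_i) / tau

    Dense output is sampled every ``output_stride`` time units (plus the final
    time).  Integrator failure raises with the last valid time reached.
    """
    from scipy.integrate import solve_ivp

    n = operator.n_nodes
    if init.n_nodes != n:
        raise ValueError("initial state does not match the operator dimension")
    p = params

    def rhs(t, y):
        u = y[:n]
        a = y[n:]
        du = -u - a + p.A * operator.apply(u)
        da = (p.B * u - a) / p.tau
        return np.concatenate([du, da])

    t_eval = np.arange(0.0, T, output_stride)
    if t_eval[-1] < T:
        t_eval = np.append(t_eval, T)
    sol = solve_ivp(
        rhs,
        (0.0, T),
        np.concatenate([init.u, init.a]),
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        last_t = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"time integration failed at t = {last_t}: {sol.message}")
    return FieldSeries(times=sol.t, u=sol.y[:n].T.copy(), a=sol.y[n:].T.copy())
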