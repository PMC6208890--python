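"""Neural field model definition: parameters, kernel, firing rate, initial data.

The two-variable field couples an activity variable u to a recovery variable
a through

    du/dt = -u - a + A * integral( w(d(x, x')) S(u(x') - h) ),
    tau da/dt = B u - a,

with a mexican-hat connectivity kernel

    w(d) = exp(-d^2) - c2 * exp(-gamma d^2),        c2 = 0.17, gamma = 0.2,

(short-range excitation, longer-range inhibition) and a sigmoidal firing rate
S(u) = 1 / (1 + exp(-beta u)).  Default constants A = 2, B = 0.4, h = 0.8,
tau = 3, beta = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .geometry import PlaneDomain, TorusDomain, TriMesh


@dataclass(frozen=True)
class NeuralFieldParams:
    """Model constants; defaults are the reference parameter set."""

    A: float = 2.0
    B: float = 0.4
    h: float = 0.8
    tau: float = 3.0
    beta: float = 5.0
    kernel_c2: float = 0.17
    kernel_gamma: float = 0.2

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 < self.kernel_gamma < 1):
            raise ValueError("kernel_gamma must lie in (0, 1) for a mexican-hat shape")
        if not (0 < self.kernel_c2 < 1):
            raise ValueError("kernel_c2 must lie in (0, 1)")


@dataclass
class FieldState:
    """Nodal activity u and recovery a at one instant."""

    u: np.ndarray
    a: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.u.shape != self.a.shape:
            raise ValueError("u and a must have the same length")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.a))):
            raise ValueError("field state must be finite")

    @property
    def n_nodes(self) -> int:
        return len(self.u)


def kernel_w(d, params: NeuralFieldParams | None = None):
    """Mexican-hat connectivity weight w(d) = exp(-d^2) - c2 exp(-gamma d^2).

    Even in d; positive below the zero crossing (~1.488 for the defaults),
    negative beyond it, and Gaussian-decaying to zero.  Vectorises over arrays.
    """
    p = params or NeuralFieldParams()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    d2 = d * d
    return np.exp(-d2) - p.kernel_c2 * np.exp(-p.kernel_gamma * d2)


def kernel_zero_crossing(params: NeuralFieldParams | None = None) -> float:
    """Distance d* where w changes sign: sqrt(ln(1/c2) / (1 - gamma))."""
    p = params or NeuralFieldParams()
    return float(np.sqrt(np.log(1.0 / p.kernel_c2) / (1.0 - p.kernel_gamma)))


def firing_rate_S(u, beta: float = 5.0):
    """Sigmoidal firing rate S(u) = 1 / (1 + exp(-beta u)), overflow-safe."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return expit(beta * np.asarray(u, dtype=float))


def kernel_mass(
    domain,
    distances=None,
    params: NeuralFieldParams | None = None,
    reference_node: int | None = None,
    grid: int = 256,
) -> float:
    """Total kernel weight W-bar = integral of w(d(x0, .)) over the domain.

    * :class:`PlaneDomain`: periodic trapezoidal quadrature of the
      minimal-image kernel on a fine grid (spectrally accurate).  The infinite
      plane limit is ``pi - c2 pi / gamma`` (0.15 pi for the defaults).
    * :class:`TriMesh` plus a distance matrix (or precomputed rows): the
      vertex-rule quadrature row sum at the reference node (default: node
      nearest the domain origin).
    """
    p = params or NeuralFieldParams()
    if isinstance(domain, PlaneDomain):
        L = domain.half_width
        dx = 2.0 * L / grid
        coords = -L + dx * np.arange(grid)
        X, Y = np.meshgrid(coords, coords, indexing="ij")
        # minimal image of the origin: within the fundamental cell d = |x|
        d = np.sqrt(X**2 + Y**2)
        return float(np.sum(kernel_w(d, p)) * dx * dx)
    if isinstance(domain, TriMesh):
        mesh = domain
        if distances is None:
            raise ValueError("kernel_mass on a mesh needs a distance matrix or row")
        values = distances.values if hasattr(distances, "values") else np.asarray(distances)
        if reference_node is None:
            reference_node = reference_node_near_origin(mesh)
        row = values[reference_node] if values.ndim == 2 else values
        q = mesh.node_quadrature_weights()
        return float(np.sum(q * kernel_w(row, p)))
    raise TypeError(
        "kernel_mass expects a PlaneDomain or a TriMesh (for tori, pass the "
        "triangulated mesh with its distance matrix)"
    )


def reference_node_near_origin(mesh: TriMesh) -> int:
    """Compact node index nearest the domain origin.

    The origin is (0, 0) for planar meshes and the point theta = phi = 0
    (outer equator) for tori; for generic meshes it is the first node.
    """
    pos = mesh.node_positions
    if isinstance(mesh.domain, TorusDomain):
        target = mesh.domain.embed(0.0, 0.0)
    elif isinstance(mesh.domain, PlaneDomain):
        target = np.zeros(3)
    else:
        return 0
    return int(np.argmin(np.sum((pos - target) ** 2, axis=1)))


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

@dataclass
class PatchSpec:
    """Rectangular (or node-neighbourhood) patches for the initial condition.

    ``kind`` selects the coordinate system: ``plane`` uses (x, y) rectangles
    with minimal-image offsets, ``torus`` uses (theta, phi) rectangles, and
    ``nodes`` grows geodesic neighbourhoods around seed nodes covering a given
    fraction of the mesh.  The offset of the a-patch relative to the u-patch
    sets the propagation direction (the bump moves away from the recovery
    patch).
    """

    kind: str = "plane"
    u_center: tuple = (0.0, 0.0)
    u_extent: tuple = (2.0, 2.0)
    u_level: float = 1.0
    a_center: tuple = (2.0, 0.0)
    a_extent: tuple = (2.0, 2.0)
    a_level: float = 1.5
    u_node: int = 0
    a_node: int = 0
    fraction: float = 0.01

    @classmethod
    def plane_default(cls):
        """2 x 2 u-patch at the origin, equal a-patch shifted +2 in x; levels 1 / 1.5."""
        return cls(kind="plane")

    @classmethod
    def torus_default(cls, domain=None, side: float = 2.0, shift: float = 2.0):
        """Equator patches of ~``side`` length units per side, a-patch shifted +``shift`` in phi arc.

        Angular extents are derived from the torus radii so the patches are
        roughly square in physical units (equal-angle patches are strongly
        anisotropic: one radian spans r along theta but R + r along phi at
        the outer equator).  Levels 2 (activity) and 1.5 (recovery).
        """
        from .geometry import TorusDomain

        dom = domain or TorusDomain(4.5, 2.0)
        r, ring = dom.minor_radius, dom.major_radius + dom.minor_radius
        return cls(
            kind="torus",
            u_center=(0.0, 0.0),
            u_extent=(side / r, side / ring),
            u_level=2.0,
            a_center=(0.0, shift / ring),
            a_extent=(side / r, side / ring),
            a_level=1.5,
        )

    @classmethod
    def nodes_default(cls, u_node: int, a_node: int, fraction: float = 0.01):
        """Geodesic neighbourhoods covering ``fraction`` of the nodes; levels 2 / 1.5."""
        return cls(kind="nodes", u_node=u_node, a_node=a_node, fraction=fraction,
                   u_level=2.0, a_level=1.5)


def _wrap(delta, period):
    return delta - period * np.round(delta / period)


def make_initial_condition(mesh: TriMesh, spec: PatchSpec, distances=None) -> FieldState:
    """Set u and a to their patch levels inside the patches, zero outside."""
    n = mesh.n_nodes
    u = np.zeros(n)
    a = np.zeros(n)
    if spec.kind == "plane":
        if not isinstance(mesh.domain, PlaneDomain):
            raise ValueError("plane patch spec requires a PlaneDomain mesh")
        period = mesh.domain.period
        xy = mesh.node_positions[:, :2]
        for center, extent, arr, level in (
            (spec.u_center, spec.u_extent, u, spec.u_level),
            (spec.a_center, spec.a_extent, a, spec.a_level),
        ):
            dxy = np.abs(_wrap(xy - np.asarray(center), period))
            inside = (dxy[:, 0] <= extent[0] / 2) & (dxy[:, 1] <= extent[1] / 2)
            if not inside.any():
                raise ValueError("empty initial-condition patch (no nodes inside)")
            arr[inside] = level
    elif spec.kind == "torus":
        if not isinstance(mesh.domain, TorusDomain):
            raise ValueError("torus patch spec requires a TorusDomain mesh")
        theta, phi = mesh.domain.angles(mesh.node_positions)
        for center, extent, arr, level in (
            (spec.u_center, spec.u_extent, u, spec.u_level),
            (spec.a_center, spec.a_extent, a, spec.a_level),
        ):
            dth = np.abs(_wrap(theta - center[0], 2 * np.pi))
            dph = np.abs(_wrap(phi - center[1], 2 * np.pi))
            inside = (dth <= extent[0] / 2) & (dph <= extent[1] / 2)
            if not inside.any():
                raise ValueError("empty initial-condition patch (no nodes inside)")
            arr[inside] = level
    elif spec.kind == "nodes":
        count = max(1, int(round(spec.fraction * n)))
        for seed, arr, level in ((spec.u_node, u, spec.u_level), (spec.a_node, a, spec.a_level)):
            if distances is not None:
                values = distances.values if hasattr(distances, "values") else np.asarray(distances)
                row = values[seed]
            else:
                from .geodesics import fmm_distances

                row = fmm_distances(mesh, [seed])[0]
            arr[np.argsort(row)[:count]] = level
    else:
        raise ValueError(f"unknown patch kind {spec.kind!r}")
    return FieldState(u=u, a=a, t=0.0)


# ---------------------------------------------------------------------------
# uniform steady states
# ---------------------------------------------------------------------------

def uniform_fixed_point(
    params: NeuralFieldParams, Wbar: float, all_roots: bool = False
):
    """Spatially uniform steady states of the model.

    At a uniform state the recovery equation forces a = B u, and u solves
    ``(1 + B) u = A * Wbar * S(u - h)``.  Roots are located by a sign-change
    scan plus bisection refinement; by default the lowest root is returned as
    ``(u*, a*)``; with ``all_roots=True`` a list of all such pairs.
    """
    from scipy.optimize import brentq

    p = params

    def g(u):
        return (1.0 + p.B) * u - p.A * Wbar * firing_rate_S(u - p.h, p.beta)

    lo = min(0.0, p.A * Wbar / (1 + p.B)) - 1.0
    hi = max(0.0, p.A * Wbar / (1 + p.B)) + 1.0
    grid = np.linspace(lo, hi, 4001)
    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-14))
    pairs = [(float(u), float(p.B * u)) for u in roots]
    if not pairs:
        raise RuntimeError("no uniform fixed point found in the scanned range")
    return pairs if all_roots else pairs[0]
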