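# Methods

## Model

The package simulates a two-variable neural field on a two-dimensional
domain Ω (a flat periodic square, a torus of revolution, or any closed
triangulated surface):

    ∂u/∂t = −u − a + A ∫_Ω w(d(x, x′)) S(u(x′, t) − h) dΩ(x′),
    τ ∂a/∂t = B u − a.

`u` is the mean activity of the neural population at a point, `a` a slow
recovery (negative-feedback) field that repolarises active regions and turns
stationary bumps into travelling ones.  The connectivity kernel

    w(d) = exp(−d²) − c₂ exp(−γ d²),   c₂ = 0.17, γ = 0.2,

is a mexican hat: excitatory below its zero crossing d* = √(ln(1/c₂)/(1−γ))
≈ 1.488 length units, weakly inhibitory beyond it, negligible past d ≈ 10.
The firing rate S(u) = 1/(1 + e^(−βu)) is evaluated at u − h.  Defaults
(A, B, h, τ, β) = (2, 0.4, 0.8, 3, 5); all parameters are dimensionless
model constants, τ in units of the activity time constant (which is 1), and
lengths in the units of the kernel.

The essential geometric ingredient is the metric `d`: minimal-image
Euclidean distance on the 2L-periodic plane (L = 7.5 by default), geodesic
distance on curved surfaces.  At any spatially uniform steady state the
recovery equation forces a = B·u and u solves (1+B)u = A·W̄·S(u−h), with
W̄ = ∫ w the kernel mass (0.15π ≈ 0.4712 on the plane at L = 7.5, where the
kernel tails at the half-period are below 10⁻⁴).

## Discretisation

Space is discretised by piecewise-linear collocation on a triangulation:
the field is represented by its nodal values, the equation is enforced at
the nodes, and the nonlocal integral is pulled back triangle-by-triangle to
the unit simplex by the affine map T_k(r, s) = (1−r−s)v₁ + s v₂ + r v₃
(Jacobian 2·Area) and evaluated with the three-point vertex rule
∫_σ G = [G(0,0) + G(0,1) + G(1,0)]/6.  Because the rule samples only
vertices, the whole integral regroups into a dense n×n matrix with entries
w(d_ij)·q_j, where q_j is one third of the area incident to node j; applying
it to S(u−h) gives the interaction term.  On the regular periodic Cartesian
grid every q_j equals Δx², which makes collocation *identical* to the
composite trapezoidal rule (and hence to the FFT/circular-convolution
evaluation) — the package asserts this identity to ≤10⁻¹² relative and it
explains the spectral accuracy of collocation on that grid.  A degree-2
edge-midpoint rule is available behind the same interface (kernel values at
interior points from barycentrically interpolated distances); it is
experimental and acts nonlinearly on u.

Time integration uses adaptive Runge–Kutta 4(5) (`scipy.solve_ivp`) with
absolute and relative tolerances 10⁻⁶ and dense output sampled every 1 time
unit by default.

## Geodesic backends

Surface distances come from first-order fast marching with the Tsitsiklis
linear-interpolation local solver: the arrival time at a vertex is the
minimum over supporting edges of (interpolated support time + straight
segment).  Two standard accuracy remedies are built in, both measured to be
necessary:

* **Near-source seeding.** The first-order update has a scale-invariant
  relative-error wedge near a point source; the 4-ring neighbourhood of each
  source is seeded with exact chord distances.
* **One level of edge unfolding.** Each interior edge contributes virtual
  update cones through the opposite apex of the neighbouring triangle
  (guarded by convexity of the unfolded quad so candidate paths genuinely
  cross the shared edge).  Consistent-diagonal grids otherwise lack the
  anti-diagonal characteristic directions entirely and do not converge along
  those rays.

With both, the planar backend is within 1.3% of the minimal-image metric
everywhere on a 65² grid (RMS error decreasing under refinement), and torus
equator/meridian arcs are reproduced to ~0.1%.  The endpoint terms of the
update make fast-marching distances bounded above by edge-graph Dijkstra
distances by construction; an `edge_dijkstra` backend is kept as that upper
baseline, and an `exact_plugin` slot accepts a user-registered exact
polyhedral solver.  All-pairs tables are symmetrised by averaging (raw
asymmetry recorded as a diagnostic); regular torus grids use their azimuthal
rotation symmetry so only one marching run per latitude row is needed.

Limitations: the backend is first order.  Its absolute error on the torus
grids is ~10⁻² length units at the 41k-node level, which matters for the
convergence studies below but not for the travelling-bump dynamics (the
kernel varies on unit scales).

## Convergence protocol

Accuracy is measured with the consecutive-difference protocol: the nonlocal
integral I_m of the trial field u = w(d(x₀, ·)) is evaluated at the node x₀
nearest the domain origin on a nested refinement sequence, and the error
proxy is |I_{m+1} − I_m|.  `estimate_order` reports the least-squares slope
against mesh spacing h ∝ N^(−1/2) *and* against node count N (half the
h-order in 2D); convergence plots in this field are drawn against N, and
order statements in the package's checks use the per-N convention.
Differences below 10⁻⁸ relative to the converged value are excluded as
rounding floor, and fits can be restricted to the asymptotic tail (the
79-node planar stage under-resolves the kernel, whose scale is ~1 against a
coarse spacing of ~1.7).

Study conditions (chosen once as desk-scale problem sizes and fixed):

* Regular plane: stages m = 0..5 of N_m = (2^m·8+1)², where the decay is
  geometric (local order estimates increase monotonically).
* Irregular plane: a seeded Lloyd-smoothed Delaunay mesh (~79 nodes) under
  quadrisection, stages m = 0..5, order fitted on the last three
  differences; the vertex rule is O(h²) = first order per node count there.
* Torus (R = 4.5, r = 2): nested 9·2^m × 18·2^m lattices, stages m = 0..3,
  with the geodesic field computed once on the m = 5 mesh and restricted to
  the nested lattices.  Fixing the field isolates quadrature error: the
  backend's own O(h) error otherwise dominates the sequence from stage ~3
  (floor ≈ 10⁻³ relative, measured).  Within the resolvable range both the
  polar trapezoidal rule and collocation still carry the lattice's fast
  pre-asymptotic decay, so the fitted orders (~2.5 and ~3.6 per node count)
  sit above the asymptotic regimes an exact polyhedral-geodesic solver
  resolves; distinguishing the collocation-specific O(h²) tail would need a
  second-order-accurate distance backend.

The torus mesh itself converges to the exact area 4π²Rr ≈ 355.3 at second
order in h, and discrete angle defects satisfy Gauss–Bonnet (Σ = 2πχ)
exactly.

## Travelling-bump experiments

Initial conditions follow the two-patch scheme: u raised in a rectangle at
the origin, a raised in an equally sized rectangle offset to one side; the
bump propagates away from the recovery patch.  Patch sizes are not
prescribed by the model; the package defaults are ~2×2 length-unit patches
with a +2 offset (on the torus the angular extents are scaled by 1/r and
1/(R+r) so patches are square in physical units — equal-angle patches are
strongly anisotropic and destabilise the launch on coarse grids).  On
general meshes the patches are geodesic neighbourhoods covering 1% of the
nodes around seed vertices.

Study sizes: 33² nodes, T = 250 on the plane (the bump crosses the domain
several times); 48×96 nodes, T = 400 on the torus.  Coarser tori (36×72)
pin the bump — a genuine discreteness effect of lattice dynamics, not a
model property — so the 48×96 grid is the documented condition.  Full-size
runs (65², larger tori) are supported but slower.

Bump tracking: support = nodes with u > 0.5·max(u); centroid = area-weighted
mean of support positions (circular means per coordinate on the periodic
plane), projected to the surface; tracking stops if max(u) < 0.2.  Step
lengths use the domain metric (minimal image / first-fundamental-form arcs /
chords).  Speeds are centred windowed estimates: per-sample quotients are
dominated by support-quantisation noise whenever the per-sample displacement
is below the mesh spacing, so the window baseline is chosen to span at least
three median edge lengths at the observed mean speed.  "Constant speed" is
operationalised as relative standard deviation ≤5% after discarding the
first 10% of samples.  Curvature along the path is analytic on tori,
angle-defect based otherwise.

Measured behaviour at the study conditions: the plane bump translates in −x
(opposite the recovery patch) with zero drift off the launch line on the
symmetric regular grid and strongly decreasing drift with node count on
irregular meshes; the torus bump launched on the outer equator stays within
one lattice spacing of θ = 0 and travels at constant speed (RSD ≈ 3%); on a
radially perturbed torus a diagonally launched bump follows a non-geodesic
path with spatially variable speed across regions of varying Gaussian
curvature.

## Synthetic data

All geometries are generated in-package: the generators *are* the study
conditions (grids, radii, patch levels 1/1.5 on the plane and 2/1.5 on the
torus, T = 250/400, tolerances 10⁻⁶).  The perturbed torus (tube radius
modulated by 12% with a sin 2θ·cos 3φ pattern) is a synthetic stand-in for
folded cortical geometry: closed, genus 1, with sign-changing Gaussian
curvature.  What passing tests show is that the numerical machinery
(quadrature, geodesics, tracking) behaves as analysed on these controlled
geometries; they do not validate the model against physiological data, and
real cortical meshes differ in mesh quality, scale separation and topology
(genus 0 with boundary per hemisphere).

## Degenerate inputs and numerical choices

Zero-area triangles are rejected at mesh validation (threshold 10⁻¹² of the
domain area); non-manifold OFF/PLY input loads with a warning flag;
disconnected meshes yield flagged infinite distances.  The dense operator is
guarded at 4 GiB.  Distance caches are keyed by mesh hash + backend and
recomputed (with a warning) on mismatch.  Uniform-steady-state roots are
located by sign-change scan plus bisection; when the sigmoid admits several
uniform states the lowest is returned by default.
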