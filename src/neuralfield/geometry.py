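"""Triangulated domains: periodic squares, tori, and generic closed surfaces.

The solver works on conforming triangulations with piecewise-planar elements.
Structured meshes (Cartesian periodic square, regular torus grid) are
generated here; irregular planar meshes come from a seeded Lloyd-smoothed
Delaunay mesher; arbitrary closed surfaces are read from ASCII OFF/PLY files.

Periodic planar meshes carry the full (duplicated-boundary) vertex grid plus a
``periodic_map`` that identifies each vertex with a canonical representative;
all topological queries and the collocation unknowns live on the identified
("node") set, while the triangle list refers to the raw vertex grid so element
geometry stays local.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class MeshParseError(ValueError):
    """Raised when an OFF/PLY file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class PlaneDomain:
    """Flat periodic square ``[-L, L]^2`` (opposite edges identified)."""

    half_width: float
    periodic: bool = True

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def period(self) -> float:
        return 2.0 * self.half_width

    @property
    def area(self) -> float:
        return self.period**2


@dataclass(frozen=True)
class TorusDomain:
    """Torus of revolution with major radius R and minor radius r (R > r > 0).

    Parameterised by the poloidal angle theta (around the tube) and the
    azimuthal angle phi (around the central axis):

        x = (R + r cos(theta)) cos(phi)
        y = (R + r cos(theta)) sin(phi)
        z = r sin(theta)
    """

    major_radius: float
    minor_radius: float

    def __post_init__(self):
        if not (self.major_radius > self.minor_radius > 0):
            raise ValueError("require R > r > 0")

    @property
    def area(self) -> float:
        """Exact surface area 4 pi^2 R r."""
        return 4.0 * np.pi**2 * self.major_radius * self.minor_radius

    def embed(self, theta, phi):
        """Map angles to 3D points; accepts scalars or arrays."""
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        ring = self.major_radius + self.minor_radius * np.cos(theta)
        return np.stack(
            [ring * np.cos(phi), ring * np.sin(phi), self.minor_radius * np.sin(theta)],
            axis=-1,
        )

    def angles(self, points):
        """Recover (theta, phi) for points on (or near) the surface."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        phi = np.arctan2(p[:, 1], p[:, 0])
        rho = np.hypot(p[:, 0], p[:, 1])
        theta = np.arctan2(p[:, 2], rho - self.major_radius)
        if np.ndim(points) == 1:
            return theta[0], phi[0]
        return theta, phi

    def project(self, points):
        """Radially project 3D points onto the torus surface."""
        theta, phi = self.angles(np.atleast_2d(points))
        out = self.embed(theta, phi)
        return out[0] if np.ndim(points) == 1 else out

    def gaussian_curvature(self, theta):
        """Analytic Gaussian curvature K(theta) = cos(theta) / (r (R + r cos(theta)))."""
        theta = np.asarray(theta, dtype=float)
        return np.cos(theta) / (
            self.minor_radius * (self.major_radius + self.minor_radius * np.cos(theta))
        )


@dataclass(frozen=True)
class StructuredGrid:
    """Bookkeeping for meshes whose nodes sit on a regular parameter lattice."""

    shape: tuple  # (n1, n2) lattice dimensions (distinct nodes)
    spacing: tuple  # lattice spacings (d1, d2)
    coords1: np.ndarray = field(repr=False)  # first-parameter values per row
    coords2: np.ndarray = field(repr=False)  # second-parameter values per column

    def flat_index(self, i, j):
        return np.asarray(i) * self.shape[1] + np.asarray(j)


class TriMesh:
    """Triangulated surface: vertices, triangles, optional periodic identification.

    Parameters
    ----------
    vertices : (n_v, 3) float array
        Vertex coordinates (planar meshes embed with z = 0).
    triangles : (n_t, 3) int array
        Vertex-index triples, consistently ordered.
    periodic_map : (n_v,) int array, optional
        Canonical representative for each vertex (identity away from the
        identified boundary).  ``None`` means no identification.
    domain : PlaneDomain or TorusDomain, optional
        Analytic domain the mesh discretises, when known.
    structured : StructuredGrid, optional
        Present for lattice-based meshes; enables symmetry shortcuts.
    """

    def __init__(self, vertices, triangles, periodic_map=None, domain=None, structured=None):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        self.triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")
        if periodic_map is not None:
            periodic_map = np.asarray(periodic_map, dtype=np.int64)
            if periodic_map.shape != (len(self.vertices),):
                raise ValueError("periodic_map must have one entry per vertex")
            if not np.array_equal(periodic_map[periodic_map], periodic_map):
                raise ValueError("periodic_map must be idempotent")
        self.periodic_map = periodic_map
        self.domain = domain
        self.structured = structured
        self.nonmanifold = False
        self._cache = {}

    # ------------------------------------------------------------------ sizes
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    # --------------------------------------------------- periodic identification
    @property
    def canonical(self) -> np.ndarray:
        """Canonical vertex index for every vertex (identity if non-periodic)."""
        if self.periodic_map is None:
            return np.arange(self.n_vertices)
        return self.periodic_map

    @property
    def node_ids(self) -> np.ndarray:
        """Sorted canonical representatives: one per distinct node."""
        if "node_ids" not in self._cache:
            self._cache["node_ids"] = np.unique(self.canonical)
        return self._cache["node_ids"]

    @property
    def n_nodes(self) -> int:
        """Number of distinct nodes after periodic identification."""
        return len(self.node_ids)

    @property
    def vertex_to_node(self) -> np.ndarray:
        """Compact node index (0..n_nodes-1) for every vertex."""
        if "vertex_to_node" not in self._cache:
            comp = np.full(self.n_vertices, -1, dtype=np.int64)
            comp[self.node_ids] = np.arange(self.n_nodes)
            self._cache["vertex_to_node"] = comp[self.canonical]
        return self._cache["vertex_to_node"]

    @property
    def node_positions(self) -> np.ndarray:
        """Coordinates of the distinct nodes (canonical representatives)."""
        return self.vertices[self.node_ids]

    @property
    def node_triangles(self) -> np.ndarray:
        """Triangles with vertex entries replaced by compact node indices."""
        return self.vertex_to_node[self.triangles]

    # ---------------------------------------------------------------- geometry
    @property
    def triangle_areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            v = self.vertices
            t = self.triangles
            e1 = v[t[:, 1]] - v[t[:, 0]]
            e2 = v[t[:, 2]] - v[t[:, 0]]
            self._cache["areas"] = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
        return self._cache["areas"]

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas.sum())

    def node_quadrature_weights(self) -> np.ndarray:
        """Per-node weight (1/3 of incident triangle area): the vertex-rule mass."""
        w = np.zeros(self.n_nodes)
        np.add.at(w, self.node_triangles.ravel(), np.repeat(self.triangle_areas / 3.0, 3))
        return w

    # ---------------------------------------------------------------- topology
    def _edge_table(self):
        if "edges" not in self._cache:
            nt = self.node_triangles
            raw = np.concatenate([nt[:, [0, 1]], nt[:, [1, 2]], nt[:, [2, 0]]])
            raw.sort(axis=1)
            edges, counts = np.unique(raw, axis=0, return_counts=True)
            self._cache["edges"] = edges
            self._cache["edge_counts"] = counts
        return self._cache["edges"], self._cache["edge_counts"]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges on the identified node set."""
        return self._edge_table()[0]

    @property
    def boundary_edges(self) -> np.ndarray:
        edges, counts = self._edge_table()
        return edges[counts == 1]

    @property
    def is_closed(self) -> bool:
        _, counts = self._edge_table()
        return bool(np.all(counts == 2))

    @property
    def euler_characteristic(self) -> int:
        edges, _ = self._edge_table()
        return self.n_nodes - len(edges) + self.n_triangles

    def node_incidence_counts(self) -> np.ndarray:
        """Number of triangles incident to each distinct node."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(counts, self.node_triangles.ravel(), 1)
        return counts

    def validate(self, min_area_frac: float = 1e-12):
        """Check basic invariants; raises ValueError on violation."""
        scale = max(self.total_area, 1.0)
        if np.any(self.triangle_areas < min_area_frac * scale):
            raise ValueError("degenerate (near-zero-area) triangle present")
        nt = np.sort(self.node_triangles, axis=1)
        if np.any(nt[:, 0] == nt[:, 1]) or np.any(nt[:, 1] == nt[:, 2]):
            raise ValueError("triangle with repeated node after identification")
        return self

    # ------------------------------------------------------------------- misc
    def mesh_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.round(self.vertices, 12).tobytes())
        h.update(self.triangles.tobytes())
        if self.periodic_map is not None:
            h.update(self.periodic_map.tobytes())
        return h.hexdigest()

    def __repr__(self):
        kind = type(self.domain).__name__ if self.domain is not None else "generic"
        return (
            f"TriMesh({self.n_vertices} vertices, {self.n_nodes} nodes, "
            f"{self.n_triangles} triangles, {kind})"
        )


# ---------------------------------------------------------------------------
# structured generators
# ---------------------------------------------------------------------------

def _plane_periodic_map(vertices: np.ndarray, L: float) -> np.ndarray:
    """Identify +L boundary vertices with their -L partners by coordinates."""
    xy = vertices[:, :2]
    wrapped = xy.copy()
    for axis in range(2):
        hit = np.isclose(wrapped[:, axis], L, rtol=0.0, atol=1e-9 * max(L, 1.0))
        wrapped[hit, axis] = -L
    key = np.round(wrapped, 9)
    lookup = {}
    for i, k in enumerate(map(tuple, np.round(xy, 9))):
        lookup.setdefault(k, i)
    pm = np.array([lookup[tuple(k)] for k in key], dtype=np.int64)
    return pm[pm]  # two passes flatten corner chains (+L,+L) -> (-L,-L)


def build_cartesian_plane_mesh(L: float, points_per_side: int) -> TriMesh:
    """Uniform triangulated grid on the periodic square ``[-L, L]^2``.

    Returns ``points_per_side**2`` vertices (both boundary copies retained) and
    ``2 (points_per_side - 1)**2`` triangles with a single consistent diagonal;
    opposite boundary vertices are identified through ``periodic_map`` so that
    every distinct node is incident to exactly six triangles.
    """
    p = int(points_per_side)
    if p < 2:
        raise ValueError("points_per_side must be >= 2")
    if L <= 0:
        raise ValueError("L must be positive")
    coords = np.linspace(-L, L, p)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.zeros(p * p)])

    idx = np.arange(p * p).reshape(p, p)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    # consistent diagonal from v00 to v11 in every cell
    tris = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )

    pm = _plane_periodic_map(vertices, L)
    dx = 2.0 * L / (p - 1)
    structured = StructuredGrid(
        shape=(p - 1, p - 1), spacing=(dx, dx), coords1=coords[:-1], coords2=coords[:-1]
    )
    mesh = TriMesh(vertices, tris, periodic_map=pm, domain=PlaneDomain(L), structured=structured)
    return mesh.validate()


def build_torus_mesh(domain: TorusDomain, n_theta: int, n_phi: int) -> TriMesh:
    """Regular triangulation of the torus from an (n_theta x n_phi) angle lattice.

    Nodes sit at theta_i = i * 2 pi / n_theta, phi_j = j * 2 pi / n_phi with the
    wrap-around identified (no duplicated seam vertices), giving exactly
    ``n_theta * n_phi`` nodes and twice as many triangles; the result is a
    closed genus-1 surface.
    """
    if n_theta < 3 or n_phi < 3:
        raise ValueError("n_theta and n_phi must be >= 3")
    dtheta = 2.0 * np.pi / n_theta
    dphi = 2.0 * np.pi / n_phi
    theta = dtheta * np.arange(n_theta)
    phi = dphi * np.arange(n_phi)
    TT, PP = np.meshgrid(theta, phi, indexing="ij")
    vertices = domain.embed(TT.ravel(), PP.ravel())

    i = np.repeat(np.arange(n_theta), n_phi)
    j = np.tile(np.arange(n_phi), n_theta)
    ip = (i + 1) % n_theta
    jp = (j + 1) % n_phi
    v00 = i * n_phi + j
    v10 = ip * n_phi + j
    v01 = i * n_phi + jp
    v11 = ip * n_phi + jp
    tris = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    structured = StructuredGrid(
        shape=(n_theta, n_phi), spacing=(dtheta, dphi), coords1=theta, coords2=phi
    )
    mesh = TriMesh(vertices, tris, domain=domain, structured=structured)
    return mesh.validate()


# ---------------------------------------------------------------------------
# irregular planar mesher
# ---------------------------------------------------------------------------

def build_irregular_plane_mesh(
    L: float, target_nodes: int, seed: int, smoothing_iters: int = 25
) -> TriMesh:
    """Seeded irregular triangulation of ``[-L, L]^2``.

    Boundary nodes are placed uniformly on the square boundary and held fixed;
    interior nodes start from a jittered lattice and are relaxed by Lloyd-style
    umbrella smoothing before a final Delaunay triangulation.  Interior nodes do
    not lie on a Cartesian lattice; the construction is deterministic for a
    fixed seed.  Periodicity is handled downstream through the minimal-image
    metric, so no periodic identification is attached.
    """
    from scipy.spatial import Delaunay

    if target_nodes < 10:
        raise ValueError("target_nodes must be >= 10")
    rng = np.random.default_rng(seed)
    k = max(3, int(round(np.sqrt(target_nodes))))
    side = np.linspace(-L, L, k)
    boundary = np.unique(
        np.concatenate(
            [
                np.column_stack([side, np.full(k, -L)]),
                np.column_stack([side, np.full(k, L)]),
                np.column_stack([np.full(k, -L), side]),
                np.column_stack([np.full(k, L), side]),
            ]
        ),
        axis=0,
    )
    n_int = max(4, target_nodes - len(boundary))
    g = int(np.ceil(np.sqrt(n_int)))
    h = 2.0 * L / (g + 1)
    gx = np.linspace(-L + h, L - h, g)
    GX, GY = np.meshgrid(gx, gx, indexing="ij")
    cand = np.column_stack([GX.ravel(), GY.ravel()])
    cand = cand[rng.permutation(len(cand))[:n_int]]
    interior = cand + rng.uniform(-0.35 * h, 0.35 * h, size=cand.shape)

    lim = L - 1e-6 * L
    for _ in range(smoothing_iters):
        pts = np.vstack([boundary, interior])
        tri = Delaunay(pts)
        # umbrella average over Delaunay neighbours, boundary fixed
        indptr, indices = tri.vertex_neighbor_vertices
        new_int = interior.copy()
        for a in range(len(boundary), len(pts)):
            nb = indices[indptr[a] : indptr[a + 1]]
            if len(nb):
                new_int[a - len(boundary)] = pts[nb].mean(axis=0)
        interior = np.clip(0.2 * interior + 0.8 * new_int, -lim, lim)

    pts = np.vstack([boundary, interior])
    tri = Delaunay(pts)
    simplices = tri.simplices.copy()
    # enforce counter-clockwise orientation
    e1 = pts[simplices[:, 1]] - pts[simplices[:, 0]]
    e2 = pts[simplices[:, 2]] - pts[simplices[:, 0]]
    flip = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0] < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    vertices = np.column_stack([pts, np.zeros(len(pts))])
    mesh = TriMesh(vertices, simplices, domain=PlaneDomain(L))
    return mesh.validate()


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def refine_quadrisect(mesh: TriMesh, surface: TorusDomain | None = None) -> TriMesh:
    """Split every triangle into four via edge midpoints (conforming).

    Shared edges produce shared midpoints; parent vertices keep their indices.
    If ``surface`` is given (or the mesh carries a :class:`TorusDomain`), new
    midpoints are radially reprojected onto the analytic surface so vertices
    stay on the torus while elements remain planar.  Periodic planar meshes get
    their boundary identification rebuilt geometrically.
    """
    if surface is None and isinstance(mesh.domain, TorusDomain):
        surface = mesh.domain

    tris = mesh.triangles
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    midpoints = 0.5 * (mesh.vertices[uniq[:, 0]] + mesh.vertices[uniq[:, 1]])
    if surface is not None:
        midpoints = surface.project(midpoints)
    mid_id = mesh.n_vertices + np.arange(len(uniq))
    m01, m12, m20 = (
        mid_id[inverse[: len(tris)]],
        mid_id[inverse[len(tris) : 2 * len(tris)]],
        mid_id[inverse[2 * len(tris) :]],
    )
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    new_tris = np.concatenate(
        [
            np.column_stack([a, m01, m20]),
            np.column_stack([m01, b, m12]),
            np.column_stack([m20, m12, c]),
            np.column_stack([m01, m12, m20]),
        ]
    )
    new_vertices = np.vstack([mesh.vertices, midpoints])

    pm = None
    if mesh.periodic_map is not None and isinstance(mesh.domain, PlaneDomain):
        pm = _plane_periodic_map(new_vertices, mesh.domain.half_width)

    # lattice bookkeeping does not survive the midpoint vertex ordering;
    # regenerate structured meshes with their builders when lattice indexing
    # is needed after refinement.
    out = TriMesh(new_vertices, new_tris, periodic_map=pm, domain=mesh.domain)
    return out.validate()


def refinement_schedule(m: int, base: int = 8) -> int:
    """Node count of the Cartesian plane schedule: N_m = (2^m * base + 1)^2."""
    if m < 0:
        raise ValueError("stage must be >= 0")
    return (2**m * base + 1) ** 2


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def gaussian_curvature(mesh: TriMesh, analytic: bool = False) -> np.ndarray:
    """Per-node Gaussian curvature.

    Discrete estimate: angle defect ``2 pi - sum(incident angles)`` divided by
    one third of the incident triangle area.  With ``analytic=True`` and a
    :class:`TorusDomain` attached, returns the closed form
    ``K = cos(theta) / (r (R + r cos(theta)))`` instead.
    """
    if analytic:
        if not isinstance(mesh.domain, TorusDomain):
            raise ValueError("analytic curvature requires a TorusDomain-attached mesh")
        theta, _ = mesh.domain.angles(mesh.node_positions)
        return mesh.domain.gaussian_curvature(theta)
    if not mesh.is_closed:
        raise ValueError("angle-defect curvature is undefined on boundary vertices")
    defect = angle_defects(mesh)
    return defect / (mesh.node_quadrature_weights())


def angle_defects(mesh: TriMesh) -> np.ndarray:
    """Raw angle defect 2 pi - sum(angles) per node; sums to 2 pi chi (Gauss-Bonnet)."""
    v = mesh.vertices
    t = mesh.triangles
    angsum = np.zeros(mesh.n_nodes)
    for corner in range(3):
        p0 = v[t[:, corner]]
        p1 = v[t[:, (corner + 1) % 3]]
        p2 = v[t[:, (corner + 2) % 3]]
        u1 = p1 - p0
        u2 = p2 - p0
        cosang = np.einsum("ij,ij->i", u1, u2) / (
            np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(angsum, mesh.node_triangles[:, corner], ang)
    return 2.0 * np.pi - angsum


# ---------------------------------------------------------------------------
# OFF / PLY input & output (ASCII)
# ---------------------------------------------------------------------------

def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as ASCII OFF (.off) or PLY (.ply), chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        _write_off(mesh, path)
    elif path.suffix.lower() == ".ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")


def load_mesh(path) -> TriMesh:
    """Read an ASCII OFF or PLY mesh; checks and reports closedness.

    Raises :class:`MeshParseError` naming the offending line on malformed
    input; non-manifold edges set ``mesh.nonmanifold`` and emit a warning.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0].strip().lower() if text.strip() else ""
    if path.suffix.lower() == ".off" or first == "off":
        vertices, tris = _read_off(text)
    elif path.suffix.lower() == ".ply" or first == "ply":
        vertices, tris = _read_ply(text)
    else:
        raise MeshParseError(f"line 1: unrecognised mesh format in {path.name}")
    mesh = TriMesh(vertices, tris)
    _, counts = mesh._edge_table()
    if np.any(counts > 2):
        mesh.nonmanifold = True
        warnings.warn(f"{path.name}: mesh has non-manifold edges", stacklevel=2)
    return mesh


def _write_off(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for v in mesh.vertices:
            f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _write_ply(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as f:
        f.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {mesh.n_vertices}\n"
            "property float x\nproperty float y\nproperty float z\n"
            f"element face {mesh.n_triangles}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v in mesh.vertices:
            f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _tokens(text):
    """Yield (line_number, token_list) skipping blanks and comments."""
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if stripped:
            yield ln, stripped.split()


def _read_off(text):
    it = _tokens(text)
    try:
        ln, tok = next(it)
    except StopIteration:
        raise MeshParseError("line 1: empty OFF file") from None
    if tok[0].upper() != "OFF":
        raise MeshParseError(f"line {ln}: expected 'OFF' header, got {tok[0]!r}")
    if len(tok) > 1:
        counts_tok, counts_ln = tok[1:], ln
    else:
        counts_ln, counts_tok = next(it, (None, None))
        if counts_tok is None:
            raise MeshParseError(f"line {ln}: missing vertex/face counts")
    try:
        nv, nf = int(counts_tok[0]), int(counts_tok[1])
    except (ValueError, IndexError):
        raise MeshParseError(f"line {counts_ln}: malformed count row") from None
    vertices = np.empty((nv, 3))
    for i in range(nv):
        ln, tok = next(it, (None, None))
        if tok is None:
            raise MeshParseError(f"line {ln or '?'}: unexpected end of file in vertex block")
        try:
            vertices[i] = [float(tok[0]), float(tok[1]), float(tok[2])]
        except (ValueError, IndexError):
            raise MeshParseError(f"line {ln}: malformed vertex row") from None
    tris = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        ln, tok = next(it, (None, None))
        if tok is None:
            raise MeshParseError("unexpected end of file in face block")
        try:
            k = int(tok[0])
        except ValueError:
            raise MeshParseError(f"line {ln}: malformed face row") from None
        if k != 3 or len(tok) < 4:
            raise MeshParseError(f"line {ln}: only triangular faces supported (got {k} indices)")
        tris[i] = [int(tok[1]), int(tok[2]), int(tok[3])]
    return vertices, tris


def _read_ply(text):
    lines = text.splitlines()
    if not lines or lines[0].strip().lower() != "ply":
        raise MeshParseError("line 1: expected 'ply' magic")
    nv = nf = None
    elements = []  # order of elements in the body
    header_end = None
    for ln, line in enumerate(lines[1:], start=2):
        tok = line.strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise MeshParseError(f"line {ln}: only ascii PLY supported")
        elif tok[0] == "element":
            if tok[1] == "vertex":
                nv = int(tok[2])
                elements.append(("vertex", nv))
            elif tok[1] == "face":
                nf = int(tok[2])
                elements.append(("face", nf))
            else:
                elements.append((tok[1], int(tok[2])))
        elif tok[0] == "end_header":
            header_end = ln
            break
    if header_end is None or nv is None or nf is None:
        raise MeshParseError("line 1: incomplete PLY header")
    body = [
        (ln, line.strip().split())
        for ln, line in enumerate(lines[header_end:], start=header_end + 1)
        if line.strip()
    ]
    pos = 0
    vertices = np.empty((nv, 3))
    tris = np.empty((nf, 3), dtype=np.int64)
    for name, count in elements:
        for i in range(count):
            if pos >= len(body):
                raise MeshParseError(f"unexpected end of file in {name} block")
            ln, tok = body[pos]
            pos += 1
            if name == "vertex":
                try:
                    vertices[i] = [float(tok[0]), float(tok[1]), float(tok[2])]
                except (ValueError, IndexError):
                    raise MeshParseError(f"line {ln}: malformed vertex row") from None
            elif name == "face":
                try:
                    k = int(tok[0])
                except ValueError:
                    raise MeshParseError(f"line {ln}: malformed face row") from None
                if k != 3 or len(tok) < 4:
                    raise MeshParseError(f"line {ln}: only triangular faces supported")
                tris[i] = [int(tok[1]), int(tok[2]), int(tok[3])]
    return vertices, tris
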