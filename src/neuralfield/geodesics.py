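"""Geodesic distances for the connectivity kernel.

The nonlocal coupling needs the distance d(x, x') between every pair of
collocation nodes.  On the flat periodic square this is the minimal-image
Euclidean distance, available in closed form.  On triangulated surfaces the
default backend is first-order fast marching with the Tsitsiklis
linear-interpolation local solver (monotone, and never worse than the
edge-graph update, so fast-marching distances are bounded above by Dijkstra
distances on the edge graph).  A slot for an exact polyhedral-geodesic
plug-in is provided but no exact solver ships with the package.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from math import inf, sqrt
from pathlib import Path

import numpy as np

from .geometry import TorusDomain, TriMesh

BACKENDS = ("fast_marching", "edge_dijkstra", "exact_plugin")

#: registry for user-supplied exact polyhedral geodesic solvers;
#: a plug-in is a callable (mesh, source_node) -> (n_nodes,) distances.
EXACT_BACKENDS: dict[str, object] = {}


# ---------------------------------------------------------------------------
# analytic periodic-plane metric
# ---------------------------------------------------------------------------

def periodic_plane_distance(p, q, L: float):
    """Minimal-image distance on the flat 2L-periodic square.

    Both points must lie in the fundamental domain ``[-L, L]^2``; the distance
    is the Euclidean norm of the displacement wrapped into ``[-L, L)`` per
    coordinate, which makes it invariant under translating both points
    modulo 2L.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    tol = 1e-9 * max(L, 1.0)
    for name, pts in (("p", p), ("q", q)):
        if np.any(np.abs(pts[..., :2]) > L + tol):
            raise ValueError(f"{name} lies outside the fundamental domain [-L, L]^2")
    delta = p[..., :2] - q[..., :2]
    period = 2.0 * L
    delta = delta - period * np.round(delta / period)
    return np.sqrt(np.sum(delta**2, axis=-1))


def plane_distance_rows(points, sources, L: float) -> np.ndarray:
    """Minimal-image distances from each source point to all points: (n_src, n)."""
    points = np.asarray(points, dtype=float)[:, :2]
    sources = np.atleast_2d(np.asarray(sources, dtype=float))[:, :2]
    period = 2.0 * L
    delta = points[None, :, :] - sources[:, None, :]
    delta -= period * np.round(delta / period)
    return np.sqrt(np.sum(delta**2, axis=-1))


# ---------------------------------------------------------------------------
# distance matrix container
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetrised all-pairs node distances with provenance.

    ``max_asymmetry`` records the largest |d_ij - d_ji| of the raw backend
    output before averaging; it is a diagnostic of backend consistency.
    """

    values: np.ndarray
    backend_name: str
    mesh_hash: str
    max_asymmetry: float = 0.0

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# fast marching
# ---------------------------------------------------------------------------

def _fmm_adjacency(mesh: TriMesh):
    """Per-node update stencils.

    For every (triangle, target-corner) pair we store
    ``(target, supportA, supportB, |C-A|, |C-B|, |A-B|)`` on the identified
    node graph, and index the pair under both support nodes: when a support
    is accepted, the target is re-examined.  Geometry is taken from the raw
    (unidentified) vertices so periodic duplicates each contribute their own
    local chart.
    """
    if "_fmm_adj" in mesh._cache:
        return mesh._cache["_fmm_adj"]
    v = mesh.vertices
    tris = mesh.triangles
    node = mesh.vertex_to_node
    adj = [[] for _ in range(mesh.n_nodes)]
    e = {
        (i, j): np.linalg.norm(v[tris[:, i]] - v[tris[:, j]], axis=1)
        for i, j in ((0, 1), (1, 2), (2, 0))
    }
    length = {}
    for (i, j), arr in e.items():
        length[(i, j)] = arr
        length[(j, i)] = arr

    def add(target, sup_a, sup_b, lca, lcb, lab):
        tup = (target, sup_a, sup_b, float(lca), float(lcb), float(lab))
        adj[sup_a].append(tup)
        adj[sup_b].append(tup)

    # direct stencils: each triangle updates each corner from the other two
    edge_owner: dict[tuple, tuple] = {}
    for t in range(len(tris)):
        nd = (node[tris[t, 0]], node[tris[t, 1]], node[tris[t, 2]])
        for target in range(3):
            ia, ib = (target + 1) % 3, (target + 2) % 3
            add(nd[target], nd[ia], nd[ib],
                length[(target, ia)][t], length[(target, ib)][t], length[(ia, ib)][t])
        # collect shared raw edges for the unfolding pass
        for ia, ib in ((0, 1), (1, 2), (2, 0)):
            key = (min(tris[t, ia], tris[t, ib]), max(tris[t, ia], tris[t, ib]))
            if key in edge_owner:
                _add_unfolded_stencils(v, tris, node, add, key, edge_owner.pop(key), t)
            else:
                edge_owner[key] = t
    mesh._cache["_fmm_adj"] = adj
    return adj


def _add_unfolded_stencils(v, tris, node, add, edge, t1, t2):
    """Virtual stencils across a shared edge (one unfolding level).

    Unfolding the two triangles sharing edge (a, b) into a common plane adds,
    for each apex, update cones through the opposite apex.  This supplies the
    "diagonal" characteristic directions a consistent-diagonal grid lacks.
    Stencils are only added when the unfolded quad is convex, so the straight
    candidate path genuinely crosses the shared edge (no underestimation).
    """
    from math import hypot

    a, b = int(edge[0]), int(edge[1])
    apex1 = next(int(x) for x in tris[t1] if x != a and x != b)
    apex2 = next(int(x) for x in tris[t2] if x != a and x != b)
    A, B = v[a], v[b]
    AB = B - A
    c = float(np.linalg.norm(AB))
    if c <= 0.0:
        return

    def local(P, sign):
        px = float(np.dot(P - A, AB)) / c
        py2 = float(np.dot(P - A, P - A)) - px * px
        return px, sign * sqrt(max(py2, 0.0))

    cx, cy = local(v[apex1], +1.0)
    dx, dy = local(v[apex2], -1.0)
    quad = ((0.0, 0.0), (dx, dy), (c, 0.0), (cx, cy))  # A, D, B, C cyclic
    crosses = []
    for i in range(4):
        x0, y0 = quad[i]
        x1, y1 = quad[(i + 1) % 4]
        x2, y2 = quad[(i + 2) % 4]
        crosses.append((x1 - x0) * (y2 - y1) - (y1 - y0) * (x2 - x1))
    if not (all(s > 1e-14 for s in crosses) or all(s < -1e-14 for s in crosses)):
        return
    lCD = hypot(cx - dx, cy - dy)
    lCA = hypot(cx, cy)
    lCB = hypot(cx - c, cy)
    lDA = hypot(dx, dy)
    lDB = hypot(dx - c, dy)
    nA, nB, nC, nD = int(node[a]), int(node[b]), int(node[apex1]), int(node[apex2])
    add(nC, nA, nD, lCA, lCD, lDA)
    add(nC, nD, nB, lCD, lCB, lDB)
    add(nD, nA, nC, lDA, lCD, lCA)
    add(nD, nC, nB, lCD, lDB, lCB)


def _tsitsiklis_update(dA: float, dB: float, b: float, a: float, c: float) -> float:
    """Candidate distance at C from supports A, B.

    Minimises ``(1-s) dA + s dB + |C - (A + s (B - A))|`` over ``s in [0, 1]``
    (linear interpolation of arrival times along AB plus a straight segment).
    The endpoints reproduce the two edge updates, so the result never exceeds
    the Dijkstra relaxation.
    """
    best = inf
    if dA < inf:
        best = dA + b
    if dB < inf:
        cand = dB + a
        if cand < best:
            best = cand
    if dA < inf and dB < inf and c > 0.0:
        # local chart: A=(0,0), B=(c,0), C=(cx,cy>=0)
        cx = (b * b + c * c - a * a) / (2.0 * c)
        cy2 = b * b - cx * cx
        if cy2 > 0.0:
            cy = sqrt(cy2)
            q = (dB - dA) / c
            if -1.0 < q < 1.0:
                s = (cx - q * cy / sqrt(1.0 - q * q)) / c
                if 0.0 < s < 1.0:
                    dx = cx - s * c
                    cand = (1.0 - s) * dA + s * dB + sqrt(dx * dx + cy * cy)
                    if cand < best:
                        best = cand
    return best


def fmm_distances(mesh: TriMesh, source_nodes, init_rings: int = 4) -> np.ndarray:
    """Fast-marching distances from each source node to all nodes.

    Returns an array of shape ``(len(source_nodes), n_nodes)``.  The
    ``init_rings``-ring neighbourhood of each source is seeded with exact
    local (chord) distances, the standard remedy for the large relative error
    of the first-order update on the strongly curved front near a point
    source.  Unreached nodes (disconnected components) keep ``inf`` and
    trigger a warning.
    """
    adj = _fmm_adjacency(mesh)
    raw_adj = _raw_vertex_adjacency(mesh)
    rows = np.empty((len(source_nodes), mesh.n_nodes))
    for k, s in enumerate(source_nodes):
        seeds = _near_source_seeds(mesh, raw_adj, int(s), init_rings)
        rows[k] = _fmm_single(adj, mesh.n_nodes, int(s), seeds)
    if np.any(np.isinf(rows)):
        warnings.warn("mesh is disconnected: some distances are infinite", stacklevel=2)
    return rows


def _raw_vertex_adjacency(mesh: TriMesh):
    if "_raw_adj" in mesh._cache:
        return mesh._cache["_raw_adj"]
    adj = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    mesh._cache["_raw_adj"] = adj
    return adj


def _near_source_seeds(mesh: TriMesh, raw_adj, source: int, rings: int):
    """Chord-distance seed values for the raw k-ring around every copy of the source."""
    node = mesh.vertex_to_node
    v = mesh.vertices
    copies = np.flatnonzero(node == source)
    seeds: dict[int, float] = {}
    for c in copies:
        frontier = {int(c)}
        seen = {int(c)}
        for _ in range(rings):
            nxt = set()
            for x in frontier:
                nxt.update(raw_adj[x])
            nxt -= seen
            for x in nxt:
                d = float(np.linalg.norm(v[x] - v[c]))
                n = int(node[x])
                if d < seeds.get(n, inf):
                    seeds[n] = d
            seen |= nxt
            frontier = nxt
    seeds.pop(source, None)
    return seeds


def _fmm_single(adj, n_nodes: int, source: int, seeds=None) -> np.ndarray:
    dist = [inf] * n_nodes
    accepted = bytearray(n_nodes)
    dist[source] = 0.0
    heap = [(0.0, source)]
    for n, d in (seeds or {}).items():
        dist[n] = d
        heap.append((d, n))
    heapq.heapify(heap)
    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        d, x = pop(heap)
        if accepted[x] or d > dist[x]:
            continue
        accepted[x] = 1
        for tgt, na, nb, lca, lcb, lab in adj[x]:
            if accepted[tgt]:
                continue
            cand = _tsitsiklis_update(dist[na], dist[nb], lca, lcb, lab)
            if cand < dist[tgt] - 1e-15:
                dist[tgt] = cand
                push(heap, (cand, tgt))
    return np.array(dist)


def _dijkstra_rows(mesh: TriMesh, source_nodes) -> np.ndarray:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    v = mesh.vertices
    tris = mesh.triangles
    node = mesh.vertex_to_node
    ii, jj, ww = [], [], []
    for a, b in ((0, 1), (1, 2), (2, 0)):
        ii.append(node[tris[:, a]])
        jj.append(node[tris[:, b]])
        ww.append(np.linalg.norm(v[tris[:, a]] - v[tris[:, b]], axis=1))
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    ww = np.concatenate(ww)
    n = mesh.n_nodes
    # deduplicate undirected edges keeping the shortest copy
    lo = np.minimum(ii, jj)
    hi = np.maximum(ii, jj)
    order = np.lexsort((ww, hi, lo))
    lo, hi, ww = lo[order], hi[order], ww[order]
    first = np.ones(len(lo), dtype=bool)
    first[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
    lo, hi, ww = lo[first], hi[first], ww[first]
    g = coo_matrix((ww, (lo, hi)), shape=(n, n)).tocsr()
    return dijkstra(g, directed=False, indices=np.asarray(source_nodes, dtype=int))


def surface_distances(mesh: TriMesh, sources, backend: str = "fast_marching") -> np.ndarray:
    """Intrinsic distances from each source node to all mesh nodes.

    ``sources`` are compact node indices.  Backends: ``fast_marching``
    (default), ``edge_dijkstra`` (graph baseline, overestimates geodesics),
    ``exact_plugin`` (user-registered exact solver).
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if backend == "fast_marching":
        return fmm_distances(mesh, sources)
    if backend == "edge_dijkstra":
        rows = _dijkstra_rows(mesh, sources)
        if np.any(np.isinf(rows)):
            warnings.warn("mesh is disconnected: some distances are infinite", stacklevel=2)
        return rows
    if backend == "exact_plugin":
        if not EXACT_BACKENDS:
            raise ValueError(
                "no exact geodesic plug-in registered; add one to "
                "neuralfield.geodesics.EXACT_BACKENDS"
            )
        fn = next(iter(EXACT_BACKENDS.values()))
        return np.vstack([np.asarray(fn(mesh, int(s))) for s in sources])
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


# ---------------------------------------------------------------------------
# all-pairs tables
# ---------------------------------------------------------------------------

_SIZE_GUARD_BYTES = 4 * 1024**3


def all_pairs_distances(
    mesh: TriMesh, backend: str = "fast_marching", cache_path=None
) -> DistanceMatrix:
    """Symmetrised all-pairs geodesic distance matrix for the mesh nodes.

    For flat periodic meshes the analytic minimal-image metric is used
    (labelled ``analytic_plane``); regular torus grids exploit their azimuthal
    rotation symmetry so only one marching run per latitude row is needed.
    Results are cached to ``cache_path`` keyed by mesh hash + backend; a
    matching cache is reloaded bit-identically, a mismatched one is recomputed
    with a warning.
    """
    n = mesh.n_nodes
    if n * n * 8 > _SIZE_GUARD_BYTES:
        raise MemoryError(
            f"all-pairs table for {n} nodes exceeds the {_SIZE_GUARD_BYTES >> 30} GiB guard"
        )
    mesh_hash = mesh.mesh_hash()
    if cache_path is not None:
        cached = _load_cache(Path(cache_path), mesh_hash, backend)
        if cached is not None:
            return cached

    from .geometry import PlaneDomain

    if isinstance(mesh.domain, PlaneDomain) and mesh.domain.periodic and backend not in (
        "edge_dijkstra",
    ):
        pts = mesh.node_positions
        raw = plane_distance_rows(pts, pts, mesh.domain.half_width)
        label = "analytic_plane"
    elif (
        backend == "fast_marching"
        and mesh.structured is not None
        and isinstance(mesh.domain, TorusDomain)
    ):
        raw = _torus_symmetric_all_pairs(mesh)
        label = backend
    else:
        raw = surface_distances(mesh, np.arange(n), backend=backend)
        label = backend
    asym = float(np.nanmax(np.abs(raw - raw.T))) if n else 0.0
    values = 0.5 * (raw + raw.T)
    np.fill_diagonal(values, 0.0)
    dm = DistanceMatrix(values, label, mesh_hash, asym)
    if cache_path is not None:
        _save_cache(Path(cache_path), dm)
    return dm


def _torus_symmetric_all_pairs(mesh: TriMesh) -> np.ndarray:
    """All-pairs distances on a regular torus grid from one run per theta-row.

    The structured torus mesh is invariant under rotating phi by its grid
    spacing, so d((i, j), (k, l)) = d((i, 0), (k, l - j)).
    """
    n_theta, n_phi = mesh.structured.shape
    sources = [i * n_phi for i in range(n_theta)]
    rows = fmm_distances(mesh, sources)  # (n_theta, n_nodes)
    fields = rows.reshape(n_theta, n_theta, n_phi)
    out = np.empty((mesh.n_nodes, mesh.n_nodes))
    for i in range(n_theta):
        for j in range(n_phi):
            out[i * n_phi + j] = np.roll(fields[i], j, axis=1).ravel()
    return out


# ----------------------------------------------------------------- cache I/O

def _save_cache(path: Path, dm: DistanceMatrix) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as f:
        np.savez(
            f,
            values=dm.values,
            backend=np.array(dm.backend_name),
            mesh_hash=np.array(dm.mesh_hash),
            max_asymmetry=np.array(dm.max_asymmetry),
        )


def _load_cache(path: Path, mesh_hash: str, backend: str) -> DistanceMatrix | None:
    if not path.exists():
        return None
    try:
        with np.load(path, allow_pickle=False) as z:
            cached_hash = str(z["mesh_hash"])
            cached_backend = str(z["backend"])
            if cached_hash != mesh_hash or cached_backend not in (backend, "analytic_plane"):
                warnings.warn(
                    "distance cache does not match the mesh hash/backend; recomputing",
                    stacklevel=3,
                )
                return None
            return DistanceMatrix(
                z["values"], cached_backend, cached_hash, float(z["max_asymmetry"])
            )
    except Exception:
        warnings.warn("unreadable distance cache; recomputing", stacklevel=3)
        return None
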