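"""Triangulated surface meshes and geodesic (graph) distances.

The spatial backbone of the DCBC criterion is the matrix of pairwise
on-surface distances between vertices.  Following standard practice for
cortical surfaces, the geodesic distance between two vertices is
approximated by the shortest path through the mesh edge graph (Dijkstra),
with edge weights equal to the Euclidean length of each triangle edge.
Distances are only kept up to a cutoff (50 mm by default downstream), which
keeps the matrix sparse and excludes pairs that no criterion ever compares.

The module also constructs geodesic spheres (frequency-``nu`` subdivisions of
the regular icosahedron, ``10*nu**2 + 2`` vertices) which serve both as
synthetic cortical surfaces and as the parcel-center scaffolds of the random
rotated parcellations used as a null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .exceptions import MeshError, ParameterError

__all__ = [
    "SurfaceMesh",
    "WeightedEdgeGraph",
    "SparseDistanceMatrix",
    "build_edge_graph",
    "geodesic_distances",
    "average_distance_matrices",
    "make_geodesic_sphere",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Triangles as triples of vertex indices.
    radius_hint : float, optional
        Sphere radius in mm, set for synthetic spheres; ``None`` for
        arbitrary surfaces (e.g. a mid-cortical surface loaded from file).
    """

    vertices: np.ndarray
    faces: np.ndarray
    radius_hint: float | None = None

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face indices out of range")
        if f.size:
            degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if degenerate.any():
                raise MeshError(f"{int(degenerate.sum())} degenerate faces (repeated vertex)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.radius_hint is not None:
            norms = np.linalg.norm(v, axis=1)
            if not np.allclose(norms, self.radius_hint, rtol=1e-6, atol=0.0):
                raise MeshError("radius_hint set but vertices do not lie on that sphere")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_connected(self) -> bool:
        g = build_edge_graph(self)
        adj = coo_matrix(
            (np.ones(len(g.weights)), (g.edges[:, 0], g.edges[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1


@dataclass(frozen=True)
class WeightedEdgeGraph:
    """Unique undirected triangle edges with Euclidean lengths (mm)."""

    edges: np.ndarray   # (e, 2) int, edges[:, 0] < edges[:, 1]
    weights: np.ndarray  # (e,) float, strictly positive
    n_vertices: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_csr(self) -> csr_matrix:
        """Symmetric sparse adjacency with edge lengths as weights."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        return coo_matrix(
            (np.concatenate([self.weights, self.weights]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_vertices, self.n_vertices),
        ).tocsr()


@dataclass(frozen=True)
class SparseDistanceMatrix:
    """Pairwise geodesic distances up to a cutoff, stored once per pair.

    ``i < j`` element-wise; all distances lie in ``(0, cutoff_mm]``.  Pairs
    beyond the cutoff are simply absent and are never evaluated downstream —
    there is no infinity sentinel.
    """

    i: np.ndarray        # (k,) int
    j: np.ndarray        # (k,) int
    d: np.ndarray        # (k,) float, mm
    n_vertices: int
    cutoff_mm: float

    def __post_init__(self) -> None:
        i = np.asarray(self.i, dtype=np.int64)
        j = np.asarray(self.j, dtype=np.int64)
        d = np.asarray(self.d, dtype=np.float64)
        if not (len(i) == len(j) == len(d)):
            raise ParameterError("i, j, d must have equal length")
        if len(i) and not (i < j).all():
            raise ParameterError("entries must satisfy i < j")
        if len(d) and (d <= 0).any():
            raise ParameterError("stored distances must be strictly positive")
        if len(d) and (d > self.cutoff_mm * (1 + 1e-12)).any():
            raise ParameterError("stored distances exceed the cutoff")
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "j", j)
        object.__setattr__(self, "d", d)

    @property
    def n_pairs(self) -> int:
        return len(self.d)

    def to_csr(self) -> csr_matrix:
        """Symmetric sparse matrix of the stored distances."""
        return coo_matrix(
            (np.concatenate([self.d, self.d]),
             (np.concatenate([self.i, self.j]), np.concatenate([self.j, self.i]))),
            shape=(self.n_vertices, self.n_vertices),
        ).tocsr()

    def lookup(self, a: int, b: int) -> float | None:
        """Distance between ``a`` and ``b``, or ``None`` if beyond cutoff."""
        if a == b:
            return 0.0
        lo, hi = (a, b) if a < b else (b, a)
        hit = (self.i == lo) & (self.j == hi)
        idx = np.flatnonzero(hit)
        return float(self.d[idx[0]]) if len(idx) else None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_edge_graph(mesh: SurfaceMesh) -> WeightedEdgeGraph:
    """Extract the unique undirected edges of a mesh with Euclidean lengths."""
    if mesh.n_faces == 0:
        raise MeshError("mesh has no faces; edge graph is undefined")
    f = mesh.faces
    raw = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    raw.sort(axis=1)
    edges = np.unique(raw, axis=0)
    diffs = mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]]
    weights = np.linalg.norm(diffs, axis=1)
    if (weights <= 0).any():
        raise MeshError("coincident vertices produce zero-length edges")
    return WeightedEdgeGraph(edges=edges, weights=weights, n_vertices=mesh.n_vertices)


def geodesic_distances(
    mesh: SurfaceMesh,
    cutoff_mm: float,
    *,
    chunk_size: int = 512,
) -> SparseDistanceMatrix:
    """All-pairs graph shortest-path distances up to ``cutoff_mm``.

    Runs Dijkstra from every vertex over the triangle edge graph, in source
    chunks to bound memory on large meshes.  A pair (i, j) is stored iff its
    shortest-path distance d satisfies 0 < d <= cutoff_mm.
    """
    if cutoff_mm <= 0:
        raise ParameterError(f"cutoff_mm must be positive, got {cutoff_mm}")
    graph = build_edge_graph(mesh).to_csr()
    n = mesh.n_vertices
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    dd: list[np.ndarray] = []
    for start in range(0, n, chunk_size):
        sources = np.arange(start, min(start + chunk_size, n))
        dmat = dijkstra(graph, directed=False, indices=sources, limit=cutoff_mm)
        rows, cols = np.nonzero(np.isfinite(dmat))
        src = sources[rows]
        keep = src < cols  # store each unordered pair once; drops d(i,i)=0
        ii.append(src[keep])
        jj.append(cols[keep])
        dd.append(dmat[rows[keep], cols[keep]])
    i = np.concatenate(ii) if ii else np.empty(0, dtype=np.int64)
    j = np.concatenate(jj) if jj else np.empty(0, dtype=np.int64)
    d = np.concatenate(dd) if dd else np.empty(0, dtype=np.float64)
    # infinite-distance components never reach here: nonzero+finite filtered
    order = np.lexsort((j, i))
    return SparseDistanceMatrix(
        i=i[order], j=j[order], d=d[order], n_vertices=n, cutoff_mm=float(cutoff_mm)
    )


def average_distance_matrices(
    matrices: list[SparseDistanceMatrix],
) -> SparseDistanceMatrix:
    """Available-case mean of several distance matrices.

    A pair is kept if present in at least one input; its value is the mean
    over the inputs in which it is present.  Inputs must share vertex count
    and cutoff (matched vertex indexing, e.g. a symmetric surface template,
    is the caller's responsibility and is *not* inferred).
    """
    if not matrices:
        raise ParameterError("need at least one distance matrix")
    n = matrices[0].n_vertices
    cutoff = matrices[0].cutoff_mm
    for m in matrices[1:]:
        if m.n_vertices != n:
            raise ParameterError("all matrices must share n_vertices")
        if m.cutoff_mm != cutoff:
            raise ParameterError("all matrices must share the cutoff")
    total = None
    count = None
    for m in matrices:
        ones = np.ones(m.n_pairs)
        s = coo_matrix((m.d, (m.i, m.j)), shape=(n, n)).tocsr()
        c = coo_matrix((ones, (m.i, m.j)), shape=(n, n)).tocsr()
        total = s if total is None else total + s
        count = c if count is None else count + c
    count = count.tocoo()
    mean = np.asarray(total.tocsr()[count.row, count.col]).ravel() / count.data
    order = np.lexsort((count.col, count.row))
    return SparseDistanceMatrix(
        i=count.row[order].astype(np.int64),
        j=count.col[order].astype(np.int64),
        d=mean[order],
        n_vertices=n,
        cutoff_mm=cutoff,
    )


# ---------------------------------------------------------------------------
# Geodesic sphere construction
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Regular icosahedron: 12 unit-ish vertices, 20 faces (fixed ordering)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def make_geodesic_sphere(frequency: int, radius_mm: float = 100.0) -> SurfaceMesh:
    """Frequency-``nu`` geodesic subdivision of the icosahedron on a sphere.

    Each icosahedron edge is split into ``frequency`` segments and each face
    into ``frequency**2`` triangles; all points are projected to the sphere
    of radius ``radius_mm``.  Vertex ordering is canonical and deterministic:
    the 12 base vertices first, then edge-interior points (edges in sorted
    order, parameter increasing from the lower-index endpoint), then
    face-interior points (faces in definition order, row-major barycentric
    grid), so identical calls are bit-reproducible.

    The result has ``10*frequency**2 + 2`` vertices and
    ``20*frequency**2`` faces.
    """
    if not isinstance(frequency, (int, np.integer)) or frequency < 1:
        raise ParameterError(f"frequency must be a positive integer, got {frequency!r}")
    if radius_mm <= 0:
        raise ParameterError(f"radius_mm must be positive, got {radius_mm}")
    nu = int(frequency)
    base_v, base_f = _icosahedron()

    coords: list[np.ndarray] = [base_v]
    # edge-interior points
    raw = np.concatenate([base_f[:, [0, 1]], base_f[:, [1, 2]], base_f[:, [0, 2]]])
    raw.sort(axis=1)
    base_edges = np.unique(raw, axis=0)
    edge_start: dict[tuple[int, int], int] = {}
    next_idx = 12
    if nu > 1:
        pts = []
        t = np.arange(1, nu)[:, None] / nu
        for a, b in base_edges:
            edge_start[(int(a), int(b))] = next_idx
            pts.append((1 - t) * base_v[a] + t * base_v[b])
            next_idx += nu - 1
        coords.append(np.concatenate(pts))

    # face-interior points and the per-face grid index map
    def edge_point(a: int, b: int, t: int) -> int:
        """Global index of the t-th interior point walking a -> b (1<=t<nu)."""
        if a < b:
            return edge_start[(a, b)] + (t - 1)
        return edge_start[(b, a)] + (nu - t - 1)

    faces_out: list[list[int]] = []
    interior_pts: list[np.ndarray] = []
    for fa, fb, fc in base_f:
        fa, fb, fc = int(fa), int(fb), int(fc)
        grid = {}
        for ib in range(nu + 1):
            for jc in range(nu + 1 - ib):
                if (ib, jc) == (0, 0):
                    grid[(ib, jc)] = fa
                elif (ib, jc) == (nu, 0):
                    grid[(ib, jc)] = fb
                elif (ib, jc) == (0, nu):
                    grid[(ib, jc)] = fc
                elif jc == 0:
                    grid[(ib, jc)] = edge_point(fa, fb, ib)
                elif ib == 0:
                    grid[(ib, jc)] = edge_point(fa, fc, jc)
                elif ib + jc == nu:
                    grid[(ib, jc)] = edge_point(fb, fc, jc)
                else:
                    grid[(ib, jc)] = next_idx
                    interior_pts.append(
                        base_v[fa]
                        + (ib / nu) * (base_v[fb] - base_v[fa])
                        + (jc / nu) * (base_v[fc] - base_v[fa])
                    )
                    next_idx += 1
        for ib in range(nu):
            for jc in range(nu - ib):
                faces_out.append([grid[(ib, jc)], grid[(ib + 1, jc)], grid[(ib, jc + 1)]])
                if ib + jc < nu - 1:
                    faces_out.append(
                        [grid[(ib + 1, jc)], grid[(ib + 1, jc + 1)], grid[(ib, jc + 1)]]
                    )

    if interior_pts:
        coords.append(np.array(interior_pts))
    vertices = np.concatenate(coords)
    vertices *= radius_mm / np.linalg.norm(vertices, axis=1, keepdims=True)
    return SurfaceMesh(
        vertices=vertices,
        faces=np.array(faces_out, dtype=np.int64),
        radius_hint=float(radius_mm),
    )
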