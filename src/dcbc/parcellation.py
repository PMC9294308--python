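"""Vertex-wise parcellations, rotated-sphere null parcellations, adjacency,
and spectral-clustering parcellation.

A parcellation assigns each surface vertex a non-negative integer label;
label 0 marks unassigned vertices (medial wall, missing data).  Two
parcellations families are generated here:

* **Rotated icosahedral parcellations** — the null model for the DCBC.  The
  vertices of a frequency-``nu`` geodesic sphere (``10*nu**2 + 2`` of them)
  act as parcel centers; rotating the centers by random angles about the
  x, y and z axes and re-assigning surface vertices to the nearest rotated
  center yields parcellations that are, on average, unaligned with any
  functional boundary structure.
* **Spectral-clustering parcellations** — a data-driven parcellation used as
  a noise ceiling: profiles are pooled onto a coarse geodesic sphere,
  clustered on a correlation affinity, and the labels propagated back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, ParameterError
from .mesh import SurfaceMesh, build_edge_graph, make_geodesic_sphere

__all__ = [
    "Parcellation",
    "ParcelAdjacency",
    "RotationSpec",
    "icosahedron_parcellation",
    "rotate_parcellation",
    "random_parcellation_set",
    "parcel_adjacency",
    "nearest_center_map",
    "spectral_parcellation",
    "ICOSAHEDRAL_PARCEL_COUNTS",
]

#: Parcel counts of the icosahedral null parcellations (10*nu^2+2, nu=2..10).
ICOSAHEDRAL_PARCEL_COUNTS = (42, 162, 362, 642, 1002)


@dataclass
class Parcellation:
    """Integer label per vertex; 0 = unassigned (e.g. medial wall)."""

    labels: np.ndarray
    name: str = ""
    centers: np.ndarray | None = None  # parcel centers, set for icosahedral maps

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.array_equal(lab, lab.astype(np.int64)):
                raise ParameterError("labels must be integers")
        lab = lab.astype(np.int64)
        if lab.ndim != 1:
            raise ParameterError("labels must be a 1-D vector")
        if lab.size and lab.min() < 0:
            raise ParameterError("labels must be non-negative")
        self.labels = lab

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def parcel_ids(self) -> np.ndarray:
        """Sorted non-empty, non-zero labels."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)


@dataclass(frozen=True)
class ParcelAdjacency:
    """For each non-zero label, the set of non-zero labels sharing a mesh edge."""

    neighbors: dict[int, frozenset[int]]

    def __getitem__(self, label: int) -> frozenset[int]:
        return self.neighbors[label]


@dataclass(frozen=True)
class RotationSpec:
    """Rotation by three angles about x, y, z, composed as Rz @ Ry @ Rx.

    Angles are drawn independently and uniformly on [0, 2*pi); note this is
    the stated sampling scheme of the null model, not a uniform distribution
    on SO(3).
    """

    angle_x: float
    angle_y: float
    angle_z: float
    seed: int | None = None

    @property
    def matrix(self) -> np.ndarray:
        cx, sx = np.cos(self.angle_x), np.sin(self.angle_x)
        cy, sy = np.cos(self.angle_y), np.sin(self.angle_y)
        cz, sz = np.cos(self.angle_z), np.sin(self.angle_z)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    @classmethod
    def random(cls, rng: np.random.Generator, seed: int | None = None) -> "RotationSpec":
        ax, ay, az = rng.uniform(0.0, 2.0 * np.pi, size=3)
        return cls(angle_x=float(ax), angle_y=float(ay), angle_z=float(az), seed=seed)


# ---------------------------------------------------------------------------
# Nearest-center assignment
# ---------------------------------------------------------------------------

def _sphere_radius(mesh: SurfaceMesh) -> float:
    norms = np.linalg.norm(mesh.vertices, axis=1)
    r = norms.mean()
    if not np.allclose(norms, r, rtol=1e-5):
        raise GeometryError("mesh vertices do not lie on a common sphere")
    return float(r)


def nearest_center_map(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the nearest center for each point, on the unit sphere.

    Both point sets are radially normalized first, so the ordering is the
    great-circle ordering for points on a common sphere.  Ties break toward
    the lowest center index (``argmin`` keeps the first minimum).
    """
    p = points / np.linalg.norm(points, axis=1, keepdims=True)
    c = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    # squared chord distance = 2 - 2*cos(angle); maximize the dot product
    # instead; np.argmax returns the first maximum, i.e. the lowest index,
    # on exact ties.  Chunked over points to bound memory on large meshes.
    out = np.empty(len(p), dtype=np.int64)
    for start in range(0, len(p), 4096):
        out[start : start + 4096] = np.argmax(p[start : start + 4096] @ c.T, axis=1)
    return out


def _assign_to_centers(mesh_vertices: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return nearest_center_map(mesh_vertices, centers) + 1


# ---------------------------------------------------------------------------
# Icosahedral null parcellations
# ---------------------------------------------------------------------------

def icosahedron_parcellation(sphere_mesh: SurfaceMesh, n_parcels: int) -> Parcellation:
    """Label each vertex of a spherical mesh by its nearest icosahedral center.

    ``n_parcels`` must be of the form ``10*nu**2 + 2``; the parcel centers
    are the vertices of the frequency-``nu`` geodesic sphere scaled to the
    mesh radius.  Labels run 1..n_parcels; on meshes coarser than the center
    set some parcels may be empty.
    """
    nu_sq = (n_parcels - 2) / 10
    nu = int(round(np.sqrt(nu_sq))) if nu_sq > 0 else 0
    if nu < 1 or 10 * nu * nu + 2 != n_parcels:
        raise ParameterError(
            f"n_parcels must be 10*nu^2+2 for integer nu >= 1, got {n_parcels}"
        )
    radius = _sphere_radius(sphere_mesh)
    centers = make_geodesic_sphere(nu, radius).vertices
    labels = _assign_to_centers(sphere_mesh.vertices, centers)
    return Parcellation(
        labels=labels, name=f"icosahedron-{n_parcels}", centers=centers
    )


def rotate_parcellation(
    parcellation: Parcellation, sphere_mesh: SurfaceMesh, rotation: RotationSpec
) -> Parcellation:
    """Rotate the parcel centers and re-assign vertices to the nearest one.

    Parcel identity is preserved: center k keeps label k+1 whether or not any
    vertex maps to it after rotation (empty parcels are not renumbered).
    """
    if parcellation.centers is None:
        raise ParameterError("parcellation has no stored centers to rotate")
    _sphere_radius(sphere_mesh)
    rotated = parcellation.centers @ rotation.matrix.T
    labels = _assign_to_centers(sphere_mesh.vertices, rotated)
    return Parcellation(
        labels=labels,
        name=f"{parcellation.name}-rot",
        centers=rotated,
    )


def random_parcellation_set(
    sphere_mesh: SurfaceMesh,
    n_parcels: int,
    n_repeats: int,
    master_seed: int,
) -> list[Parcellation]:
    """``n_repeats`` independently rotated icosahedral parcellations.

    All rotations are drawn from a single generator seeded with
    ``master_seed``, so the whole set is reproducible bit-for-bit.
    """
    if n_repeats < 1:
        raise ParameterError(f"n_repeats must be >= 1, got {n_repeats}")
    base = icosahedron_parcellation(sphere_mesh, n_parcels)
    rng = np.random.default_rng(master_seed)
    out = []
    for k in range(n_repeats):
        rot = RotationSpec.random(rng, seed=master_seed)
        p = rotate_parcellation(base, sphere_mesh, rot)
        p.name = f"icosahedron-{n_parcels}-rand{k}"
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Parcel adjacency
# ---------------------------------------------------------------------------

def parcel_adjacency(parcellation: Parcellation, mesh: SurfaceMesh) -> ParcelAdjacency:
    """Parcels sharing at least one mesh edge; label 0 excluded entirely."""
    if parcellation.n_vertices != mesh.n_vertices:
        raise ParameterError("parcellation and mesh vertex counts differ")
    edges = build_edge_graph(mesh).edges
    la = parcellation.labels[edges[:, 0]]
    lb = parcellation.labels[edges[:, 1]]
    keep = (la != lb) & (la > 0) & (lb > 0)
    neighbors: dict[int, set[int]] = {int(k): set() for k in parcellation.parcel_ids}
    for a, b in zip(la[keep], lb[keep]):
        neighbors[int(a)].add(int(b))
        neighbors[int(b)].add(int(a))
    return ParcelAdjacency(
        neighbors={k: frozenset(v) for k, v in neighbors.items()}
    )


# ---------------------------------------------------------------------------
# Spectral-clustering parcellation (noise-ceiling procedure)
# ---------------------------------------------------------------------------

def spectral_parcellation(
    profiles,
    mesh: SurfaceMesh,
    k: int,
    downsample_frequency: int = 20,
    random_state: int = 0,
) -> Parcellation:
    """Data-driven parcellation by spectral clustering at reduced resolution.

    1. Pool functional profiles onto the frequency-``downsample_frequency``
       geodesic sphere (4002 vertices at the default) by averaging each
       vertex's profile into its nearest center.
    2. Spectral clustering with ``k`` clusters on the affinity matrix:
       Pearson correlation between pooled profiles, negatives clipped to 0,
       zero diagonal (k-means on the leading eigenvectors of the normalized
       graph Laplacian, fixed ``random_state``).
    3. Propagate cluster labels back to full resolution through the same
       nearest-center map.

    Cluster label permutation is arbitrary; compare results with a
    permutation-invariant score (e.g. adjusted Rand index).
    """
    from sklearn.cluster import SpectralClustering

    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    values = np.asarray(profiles.values, dtype=np.float64)
    valid = np.asarray(profiles.valid_mask, dtype=bool)
    if len(values) != mesh.n_vertices:
        raise ParameterError("profiles and mesh vertex counts differ")
    radius = _sphere_radius(mesh)
    centers = make_geodesic_sphere(downsample_frequency, radius).vertices
    assign = nearest_center_map(mesh.vertices, centers)

    n_centers = len(centers)
    pooled = np.zeros((n_centers, values.shape[1]))
    counts = np.zeros(n_centers)
    np.add.at(pooled, assign[valid], values[valid])
    np.add.at(counts, assign[valid], 1.0)
    used = counts > 0
    node_idx = np.flatnonzero(used)
    if k > len(node_idx):
        raise ParameterError(
            f"k={k} exceeds the {len(node_idx)} populated downsampled vertices"
        )
    pooled = pooled[used] / counts[used, None]

    if k == 1:
        node_labels = np.zeros(len(node_idx), dtype=np.int64)
    else:
        affinity = np.corrcoef(pooled)
        affinity = np.nan_to_num(affinity, nan=0.0)
        np.clip(affinity, 0.0, None, out=affinity)
        np.fill_diagonal(affinity, 0.0)
        sc = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            assign_labels="kmeans",
            random_state=random_state,
        )
        node_labels = sc.fit_predict(affinity)

    center_label = np.zeros(n_centers, dtype=np.int64)
    center_label[node_idx] = node_labels + 1
    labels = center_label[assign]
    labels[~valid] = 0
    return Parcellation(labels=labels, name=f"spectral-k{k}")
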