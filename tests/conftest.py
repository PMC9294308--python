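import numpy as np
import pytest
from scipy.spatial import Delaunay

import dcbc


@pytest.fixture(scope="session")
def sphere8():
    """Frequency-8 geodesic sphere (642 vertices), fsLR-like 100 mm radius."""
    return dcbc.make_geodesic_sphere(8, 100.0)


@pytest.fixture(scope="session")
def sphere8_dist(sphere8):
    return dcbc.geodesic_distances(sphere8, 50.0)


@pytest.fixture(scope="session")
def sphere2():
    """Frequency-2 sphere (42 vertices) for exhaustive-oracle comparisons."""
    return dcbc.make_geodesic_sphere(2, 100.0)


@pytest.fixture(scope="session")
def planar20():
    """Irregular 20-vertex triangulated patch (Delaunay of random points)."""
    rng = np.random.default_rng(42)
    pts2d = rng.uniform(0.0, 30.0, size=(20, 2))
    tri = Delaunay(pts2d)
    vertices = np.column_stack([pts2d, np.zeros(20)])
    return dcbc.SurfaceMesh(vertices=vertices, faces=tri.simplices)


@pytest.fixture(scope="session")
def toy_eval():
    """A small labelled mesh + profiles for criterion-vs-oracle tests.

    Frequency-2 sphere (42 vertices), three parcels with a few unassigned
    vertices, mildly smooth random profiles with one masked vertex.
    """
    mesh = dcbc.make_geodesic_sphere(2, 100.0)
    dist = dcbc.geodesic_distances(mesh, 120.0)
    rng = np.random.default_rng(7)
    labels = 1 + (mesh.vertices[:, 2] > 20) + 2 * (mesh.vertices[:, 2] < -20)
    labels = labels.astype(np.int64)
    labels[[0, 5]] = 0  # unassigned vertices
    values = rng.standard_normal((42, 6))
    values += 0.5 * rng.standard_normal(6)  # shared component -> correlations
    values[11] = np.nan  # masked vertex
    profiles = dcbc.FunctionalProfiles(values)
    parc = dcbc.Parcellation(labels=labels, name="toy")
    return mesh, dist, parc, profiles
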