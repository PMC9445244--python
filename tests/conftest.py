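"""Shared fixtures: small synthetic templates, graphs and hierarchies."""

from functools import lru_cache

import numpy as np
import pytest

import structage as sa


@lru_cache(maxsize=None)
def _template(structure: str, hemisphere: str = "L", seed: int = 1):
    return sa.make_template(structure, hemisphere=hemisphere, seed=seed)


@pytest.fixture(scope="session")
def template_factory():
    """Session-cached synthetic template builder (templates are deterministic)."""
    return _template


@pytest.fixture(scope="session")
def accumbens_template(template_factory):
    return template_factory("accumbens")


@pytest.fixture(scope="session")
def accumbens_graph(accumbens_template):
    return sa.mesh_to_graph(accumbens_template.mesh)


@pytest.fixture(scope="session")
def accumbens_hierarchy(accumbens_graph):
    return sa.binary_partition(accumbens_graph, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_triangle_mesh():
    """Single triangle: the smallest valid surface fragment."""
    return sa.SurfaceMesh(
        "accumbens",
        "L",
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        np.array([[0, 1, 2]]),
    )


def make_tetrahedron_mesh():
    """Tetrahedron: the smallest closed triangulation (graph is K4)."""
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return sa.SurfaceMesh("accumbens", "L", verts, faces)


def random_triangulation_graph(n: int, rng: np.random.Generator) -> sa.StructureGraph:
    """Random connected graph from a Delaunay-like construction on the sphere."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hull = ConvexHull(pts)
    mesh = sa.SurfaceMesh("accumbens", "L", pts, hull.simplices)
    return sa.mesh_to_graph(mesh)
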