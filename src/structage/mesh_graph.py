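"""Surface meshes, their graphs, Laplacians and per-node input features.

A template-registered triangulated surface is turned into an undirected
weighted graph (nodes = vertices, edges = triangle edges), from which the
symmetric-normalized Laplacian is built and rescaled so its spectrum lies in
[-1, 1] — the domain of the Chebyshev polynomials used by the convolutional
layers.  Per-node input features are the vertex coordinates (mm), centered
on the origin and divided by 100.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = [
    "STRUCTURE_LABELS",
    "TEMPLATE_NODE_COUNTS",
    "SurfaceMesh",
    "StructureGraph",
    "ScaledLaplacian",
    "MeshFormatError",
    "MeshValidationError",
    "load_mesh",
    "save_mesh",
    "mesh_to_graph",
    "scaled_laplacian",
    "build_features",
    "merge_graphs",
    "export_graph_text",
]

STRUCTURE_LABELS = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
    "cortex",
)

#: Template node counts per hemisphere; all powers of two so that stride-2
#: pooling can halve the graph repeatedly without padding.
TEMPLATE_NODE_COUNTS = {
    "accumbens": 256,
    "amygdala": 512,
    "caudate": 1024,
    "hippocampus": 2048,
    "pallidum": 512,
    "putamen": 1024,
    "thalamus": 2048,
    "cortex": 16384,
}

HEMISPHERES = ("L", "R")


class MeshFormatError(ValueError):
    """File could not be parsed as the named mesh format."""


class MeshValidationError(ValueError):
    """Mesh violates a structural invariant (indices, triangles, manifoldness)."""


@dataclass
class SurfaceMesh:
    """Template-registered triangulated surface of one structure.

    Vertex order is node identity: it must never be permuted silently, as
    the cross-subject correspondence of the template depends on it.
    """

    structure_label: str
    hemisphere: str
    vertices: np.ndarray  # (N, 3) float, millimetres
    faces: np.ndarray  # (F, 3) int, 0-based

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.structure_label not in STRUCTURE_LABELS:
            raise MeshValidationError(
                f"unknown structure label {self.structure_label!r}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise MeshValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be triangles (F, 3)")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshValidationError("face indices out of range [0, N)")
        # each undirected edge may border at most two triangles
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]]
            ),
            axis=1,
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        if counts.size and counts.max() > 2:
            raise MeshValidationError("an edge is shared by more than two faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def load_mesh(
    path: str | Path,
    structure_label: str,
    hemisphere: str = "L",
    format: str | None = None,
) -> SurfaceMesh:
    """Read an ASCII/binary PLY or OFF file, preserving vertex order exactly.

    ``format`` defaults to the file extension; it must resolve to "PLY" or
    "OFF".
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "off"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        # process=False: no vertex merging/reordering — template order is identity
        tm = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 — surface parser errors uniformly
        raise MeshFormatError(f"cannot parse {path} as {fmt.upper()}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshFormatError(f"{path} does not contain a triangle mesh")
    faces = np.asarray(tm.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshValidationError(f"{path}: non-triangular faces")
    return SurfaceMesh(structure_label, hemisphere, np.asarray(tm.vertices), faces)


def save_mesh(mesh: SurfaceMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh as ASCII PLY or OFF (extension decides by default)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "off"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type="off")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


@dataclass
class StructureGraph:
    """Undirected weighted graph of one structure, or a disjoint union of
    several (``offsets`` records the node range of each block)."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int, each row sorted i < j, unique
    weights: np.ndarray  # (E,) nonnegative float
    offsets: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (structure_label, hemisphere, start, stop)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be nonnegative")

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix."""
        n = self.n_nodes
        if len(self.edges) == 0:
            return sp.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        a = sp.coo_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (np.concatenate([i, j]), np.concatenate([j, i])),
            ),
            shape=(n, n),
        )
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def mesh_to_graph(mesh: SurfaceMesh, weighting: str = "binary") -> StructureGraph:
    """Convert a triangulation to a graph: one node per vertex, one
    undirected edge per unique triangle edge.

    ``weighting`` is "binary" (weight 1, default — purely combinatorial) or
    "inverse_length" (1 / Euclidean edge length in mm).
    """
    f = mesh.faces
    e = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]]), axis=1
    )
    edges = np.unique(e, axis=0)
    if weighting == "binary":
        w = np.ones(len(edges))
    elif weighting == "inverse_length":
        lengths = np.linalg.norm(
            mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
        )
        w = 1.0 / np.maximum(lengths, 1e-12)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return StructureGraph(
        n_nodes=mesh.n_vertices,
        edges=edges,
        weights=w,
        offsets=[(mesh.structure_label, mesh.hemisphere, 0, mesh.n_vertices)],
    )


@dataclass
class ScaledLaplacian:
    """Symmetric-normalized graph Laplacian rescaled so its spectrum lies in
    [-1, 1]:  L~ = (2 / lambda_max) L - I."""

    matrix: sp.csr_matrix
    lambda_max: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _lambda_max(L: sp.csr_matrix) -> float:
    """Largest eigenvalue of a symmetric PSD matrix.

    Lanczos iteration with a deterministic start vector; plain power
    iteration stalls on mesh graphs whose top eigenvalues are nearly
    degenerate, and the rescaled spectrum must stay inside [-1, 1] to
    ~1e-8.  Small matrices are solved densely; on failure the fallback is
    2.0, the upper bound for normalized Laplacians.
    """
    n = L.shape[0]
    if n <= 32:
        return float(np.linalg.eigvalsh(L.toarray()).max())
    v0 = np.ones(n) + 1e-3 * np.arange(n)  # deterministic start
    try:
        lam = sp.linalg.eigsh(
            L, k=1, which="LA", v0=v0, tol=1e-10, return_eigenvectors=False
        )
        return float(lam[0])
    except sp.linalg.ArpackNoConvergence:
        return 2.0


def scaled_laplacian(graph: StructureGraph | sp.spmatrix) -> ScaledLaplacian:
    """Build L = I - D^{-1/2} A D^{-1/2} and rescale to L~ = (2/lmax) L - I.

    Isolated nodes get zero rows in L (and hence -1 diagonal entries in L~,
    safely within the Chebyshev domain).  An edgeless graph uses the
    lambda_max = 2 fallback, giving L~ = -I.
    """
    A = graph.adjacency() if isinstance(graph, StructureGraph) else sp.csr_matrix(graph)
    n = A.shape[0]
    if n < 1:
        raise ValueError("graph must have at least one node")
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    D = sp.diags(dinv)
    norm_adj = D @ A @ D
    # diagonal of L is 1 for connected nodes, 0 for isolated nodes
    diag = (deg > 0).astype(np.float64)
    L = sp.diags(diag) - norm_adj
    L = (L + L.T) * 0.5  # enforce exact symmetry against rounding
    if A.nnz == 0:
        lmax = 2.0
    else:
        lmax = _lambda_max(L.tocsr())
        if not (0 < lmax <= 2 + 1e-6):
            lmax = 2.0
    Lt = (2.0 / lmax) * L - sp.identity(n, format="csr")
    return ScaledLaplacian(matrix=Lt.tocsr(), lambda_max=lmax)


def build_features(
    meshes: Sequence[SurfaceMesh],
    centering_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-node input features: (coordinates - offset) / 100.

    One mesh gives 3 columns; for the cortex, pass exactly two meshes
    (inner, outer) sharing the template order to get 6 columns.  When
    ``centering_offset`` is None the mean over all vertices of all supplied
    meshes is used (per-scan centering, which preserves the relative
    positions of structures fed jointly to a network).
    """
    if len(meshes) not in (1, 2):
        raise ValueError("expected one mesh, or two (inner, outer) for cortex")
    if len(meshes) == 2 and meshes[0].n_vertices != meshes[1].n_vertices:
        raise MeshValidationError("inner/outer vertex counts differ")
    if centering_offset is None:
        centering_offset = np.concatenate([m.vertices for m in meshes]).mean(axis=0)
    centering_offset = np.asarray(centering_offset, dtype=np.float64).reshape(3)
    cols = [(m.vertices - centering_offset) / 100.0 for m in meshes]
    return np.concatenate(cols, axis=1)


def scan_centering_offset(meshes: Iterable[SurfaceMesh]) -> np.ndarray:
    """Mean vertex coordinate over every mesh of one scan (the shared
    centering offset when several structures feed one network)."""
    allv = np.concatenate([m.vertices for m in meshes])
    return allv.mean(axis=0)


def merge_graphs(
    graphs: Sequence[StructureGraph],
    features: Sequence[np.ndarray] | None = None,
) -> tuple[StructureGraph, np.ndarray | None]:
    """Disjoint union of graphs (block-diagonal adjacency); features are
    stacked row-wise and zero-padded on the right to the widest matrix."""
    if not graphs:
        raise ValueError("merge_graphs needs at least one graph")
    if features is not None and len(features) != len(graphs):
        raise ValueError("features list must match graphs list")
    offset = 0
    edges, weights, offsets = [], [], []
    for g in graphs:
        if len(g.edges):
            edges.append(g.edges + offset)
            weights.append(g.weights)
        for (lab, hemi, a, b) in g.offsets:
            offsets.append((lab, hemi, a + offset, b + offset))
        offset += g.n_nodes
    merged = StructureGraph(
        n_nodes=offset,
        edges=np.concatenate(edges) if edges else np.empty((0, 2), dtype=np.int64),
        weights=np.concatenate(weights) if weights else np.empty(0),
        offsets=offsets,
    )
    if features is None:
        return merged, None
    width = max(f.shape[1] for f in features)
    rows = []
    for g, f in zip(graphs, features):
        f = np.asarray(f, dtype=np.float64)
        if f.shape[0] != g.n_nodes:
            raise ValueError("feature rows must match graph nodes")
        if f.shape[1] < width:
            f = np.pad(f, ((0, 0), (0, width - f.shape[1])))
        rows.append(f)
    return merged, np.concatenate(rows, axis=0)


def export_graph_text(graph: StructureGraph, path: str | Path | io.TextIOBase) -> None:
    """Dump the edge list as ``node_i node_j weight`` lines (debug aid)."""
    lines = [
        f"{i} {j} {w:.9g}\n"
        for (i, j), w in zip(graph.edges.tolist(), graph.weights.tolist())
    ]
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            fh.writelines(lines)
    else:
        path.writelines(lines)
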