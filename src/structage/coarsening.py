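"""Multiscale binary partitioning of structure graphs.

At every scale the nodes are split into adjacent pairs; each pair becomes one
node of the next, twice-coarser graph.  Permutations are derived so that the
two members of a pair sit at consecutive rows, making pooling a plain
stride-2 1D operator on the feature rows.  Node counts must be divisible by
2^n_levels (template counts are powers of two), so every matching is perfect
and no fake-node padding is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .mesh_graph import ScaledLaplacian, StructureGraph, scaled_laplacian

__all__ = [
    "CoarseningHierarchy",
    "PairingError",
    "binary_partition",
    "apply_ordering",
    "pool_features",
]

logger = logging.getLogger(__name__)


class PairingError(RuntimeError):
    """No perfect adjacent pairing could be constructed."""


@dataclass
class CoarseningHierarchy:
    """Per-scale orderings, pairings and coarse graphs.

    ``graphs[s]`` is the scale-s adjacency (scale 0 = finest); ``pairs[s]``
    is an (N_s/2, 2) array of node ids paired at scale s; ``perms[s]`` maps
    row position -> node id so that positions 2i and 2i+1 hold the members
    of the pair that becomes coarse node at position i of scale s+1.
    """

    graphs: list[sp.csr_matrix]
    pairs: list[np.ndarray]
    perms: list[np.ndarray]
    n_nonadjacent_pairs: int = 0
    _laplacians: list[ScaledLaplacian] | None = field(default=None, repr=False)

    @property
    def n_levels(self) -> int:
        return len(self.pairs)

    @property
    def node_counts(self) -> list[int]:
        return [g.shape[0] for g in self.graphs]

    def laplacian(self, scale: int) -> ScaledLaplacian:
        """Scaled Laplacian of the scale-s graph with rows/cols permuted
        into the scale-s ordering (so it matches pooled feature rows)."""
        if self._laplacians is None:
            self._laplacians = []
            for g, perm in zip(self.graphs, self.perms):
                A = g[perm][:, perm]
                self._laplacians.append(scaled_laplacian(A))
        return self._laplacians[scale]

    def save(self, path: str | Path) -> None:
        """Serialize orderings, pairs and coarse edge lists to one .npz."""
        arrays: dict[str, np.ndarray] = {"n_levels": np.array(self.n_levels)}
        for s, g in enumerate(self.graphs):
            coo = g.tocoo()
            arrays[f"graph{s}_ij"] = np.stack([coo.row, coo.col])
            arrays[f"graph{s}_w"] = coo.data
            arrays[f"graph{s}_n"] = np.array(g.shape[0])
            arrays[f"perm{s}"] = self.perms[s]
        for s, p in enumerate(self.pairs):
            arrays[f"pairs{s}"] = p
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CoarseningHierarchy":
        with np.load(path) as z:
            n_levels = int(z["n_levels"])
            graphs, perms, pairs = [], [], []
            for s in range(n_levels + 1):
                n = int(z[f"graph{s}_n"])
                ij = z[f"graph{s}_ij"]
                g = sp.coo_matrix((z[f"graph{s}_w"], (ij[0], ij[1])), shape=(n, n))
                graphs.append(g.tocsr())
                perms.append(z[f"perm{s}"])
            for s in range(n_levels):
                pairs.append(z[f"pairs{s}"])
        return cls(graphs=graphs, pairs=pairs, perms=perms)


def _greedy_heavy_edge_matching(A: sp.csr_matrix) -> dict[int, int]:
    """Greedy maximal matching: visit nodes by ascending degree (ties by
    index), pair each unmatched node with its heaviest unmatched neighbor."""
    n = A.shape[0]
    deg = np.diff(A.indptr)
    order = np.lexsort((np.arange(n), deg))  # degree asc, index asc
    mate: dict[int, int] = {}
    indptr, indices, data = A.indptr, A.indices, A.data
    for u in order:
        if u in mate:
            continue
        best, best_w = -1, -np.inf
        for idx in range(indptr[u], indptr[u + 1]):
            v = indices[idx]
            if v == u or v in mate:
                continue
            w = data[idx]
            if w > best_w or (w == best_w and v < best):
                best, best_w = v, w
        if best >= 0:
            mate[u] = best
            mate[best] = u
    return mate


def _augmenting_path_repair(A: sp.csr_matrix, mate: dict[int, int]) -> None:
    """Grow a maximal matching toward perfection by alternating-path search.

    Iterative DFS from each unmatched node over (unmatched edge, matched
    edge) alternations; augments in place when another free node is
    reached.  No blossom contraction, which is sufficient in practice on
    triangulated surface graphs.
    """
    indptr, indices = A.indptr, A.indices
    n = A.shape[0]
    for start in range(n):
        if start in mate:
            continue
        visited: set[int] = {start}  # never rediscover the root as a free end
        # stack holds (node-to-extend-from, its neighbor iterator)
        stack = [(start, iter(indices[indptr[start] : indptr[start + 1]]))]
        parent: dict[int, int] = {}
        while stack:
            u, it = stack[-1]
            advanced = False
            for v in it:
                v = int(v)
                if v in visited or v == u:
                    continue
                visited.add(v)
                parent[v] = u
                if v not in mate:
                    # flip matched/unmatched edges along start ... u - v
                    node = v
                    while node is not None:
                        even = parent[node]
                        old = mate.get(even)  # even node's previous partner
                        mate[even] = node
                        mate[node] = even
                        node = old
                    stack.clear()
                    advanced = True
                    break
                w = mate[v]
                if w not in visited:
                    visited.add(w)
                    parent[w] = v
                    stack.append((w, iter(indices[indptr[w] : indptr[w + 1]])))
                    advanced = True
                    break
            if not advanced and stack:
                stack.pop()


def _perfect_matching(A: sp.csr_matrix) -> tuple[np.ndarray, int]:
    """Perfect pairing of all nodes, adjacent wherever possible.

    Greedy heavy-edge matching first, then augmenting-path repair; if nodes
    remain unmatched, a maximum-cardinality matching (blossom) is computed
    as a last resort.  Any nodes still unmatched (pathological graphs) are
    paired with the nearest remaining node by index and counted as
    non-adjacent.
    Returns (pairs sorted by min member, count of non-adjacent pairs).
    """
    n = A.shape[0]
    if n % 2:
        raise PairingError(f"odd node count {n} cannot be perfectly paired")
    mate = _greedy_heavy_edge_matching(A)
    if len(mate) < n:
        _augmenting_path_repair(A, mate)
    if len(mate) < n:
        G = nx.from_scipy_sparse_array(A)
        mw = nx.max_weight_matching(G, maxcardinality=True)
        mate = {}
        for u, v in mw:
            mate[u] = v
            mate[v] = u
    unmatched = sorted(set(range(n)) - set(mate))
    n_bad = 0
    for a, b in zip(unmatched[::2], unmatched[1::2]):
        mate[a] = b
        mate[b] = a
        n_bad += 1
    if n_bad:
        warnings.warn(
            f"{n_bad} non-adjacent pair(s) forced during coarsening", stacklevel=3
        )
    pairs = np.array(sorted({(min(u, v), max(u, v)) for u, v in mate.items()}))
    return pairs, n_bad


def _coarsen_adjacency(A: sp.csr_matrix, pairs: np.ndarray) -> sp.csr_matrix:
    """Collapse each pair into one coarse node; coarse edge weight is the sum
    of cross-pair fine weights (heavy-edge aggregation); no self-loops."""
    n = A.shape[0]
    parent = np.empty(n, dtype=np.int64)
    for c, (u, v) in enumerate(pairs):
        parent[u] = c
        parent[v] = c
    coo = A.tocoo()
    ci, cj = parent[coo.row], parent[coo.col]
    keep = ci != cj
    nc = len(pairs)
    Ac = sp.coo_matrix((coo.data[keep], (ci[keep], cj[keep])), shape=(nc, nc))
    return Ac.tocsr()


def binary_partition(graph: StructureGraph, n_levels: int) -> CoarseningHierarchy:
    """Build the n_levels-deep pairing hierarchy of a graph.

    Requires the node count to be divisible by 2**n_levels.  Pairings are
    deterministic (ties broken by node index); for merged graphs pairs never
    cross structure blocks because blocks are disconnected.
    """
    n = graph.n_nodes
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    if n % (2**n_levels):
        raise ValueError(
            f"node count {n} is not divisible by 2^{n_levels}; "
            "pick a level count the graph can be halved into"
        )
    graphs = [graph.adjacency()]
    pairs_all: list[np.ndarray] = []
    total_bad = 0
    for s in range(n_levels):
        pairs, n_bad = _perfect_matching(graphs[s])
        total_bad += n_bad
        pairs_all.append(pairs)
        graphs.append(_coarsen_adjacency(graphs[s], pairs))
    # orderings, top-down: coarsest scale keeps index order; at scale s the
    # children of the coarse node at position i sit at positions 2i, 2i+1
    perms: list[np.ndarray] = [np.arange(graphs[-1].shape[0])] * 1
    for s in range(n_levels - 1, -1, -1):
        coarse_perm = perms[0]
        fine = np.empty(graphs[s].shape[0], dtype=np.int64)
        pr = pairs_all[s]
        for pos, c in enumerate(coarse_perm):
            fine[2 * pos] = pr[c, 0]
            fine[2 * pos + 1] = pr[c, 1]
        perms.insert(0, fine)
    hier = CoarseningHierarchy(
        graphs=graphs, pairs=pairs_all, perms=perms, n_nonadjacent_pairs=total_bad
    )
    logger.debug(
        "coarsening: %s nodes across scales, %d forced pair(s)",
        hier.node_counts,
        total_bad,
    )
    return hier


def apply_ordering(features: np.ndarray, permutation: np.ndarray) -> np.ndarray:
    """Reorder rows so that row k of the output is row permutation[k] of the
    input.  Works on (..., N, F) stacks; permutation must be a bijection."""
    permutation = np.asarray(permutation)
    n = features.shape[-2]
    if sorted(permutation.tolist()) != list(range(n)):
        raise ValueError("permutation is not a bijection on the rows")
    return np.asarray(features)[..., permutation, :]


def pool_features(features: np.ndarray, mode: str = "max") -> np.ndarray:
    """Stride-2 1D pooling over already-ordered rows: output row i combines
    rows 2i and 2i+1 (``mode`` is "max" or "mean")."""
    x = np.asarray(features)
    n = x.shape[-2]
    if n % 2:
        raise ValueError(f"row count {n} is not even")
    shaped = x.reshape(*x.shape[:-2], n // 2, 2, x.shape[-1])
    if mode == "max":
        return shaped.max(axis=-2)
    if mode == "mean":
        return shaped.mean(axis=-2)
    raise ValueError(f"unknown pooling mode {mode!r}")
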