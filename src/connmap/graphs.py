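"""Binary graph construction from correlation matrices.

A functional connectome is summarized as a binary undirected graph on N
labeled nodes (brain regions).  To guarantee that every region stays
reachable while controlling edge density, the graph is built in two steps:

1. a maximum-|r| spanning tree connects all nodes (equivalently, a minimum
   spanning tree on 1 - |r|), then
2. the remaining strongest absolute correlations are added until the graph
   holds exactly ``round(density * N(N-1)/2)`` edges.

Every subject's graph therefore has the same number of edges at a given
density, making nodal metrics comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "CorrelationMatrix",
    "BinaryGraph",
    "binarize_connectome",
    "shortest_path_lengths",
    "target_edge_count",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation matrix with labeled nodes.

    Values are unitless correlations in [-1, 1]; the diagonal is 1.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        n = len(self.node_ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        if np.isnan(values).any():
            raise ValueError("correlation matrix contains NaN")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric (tol 1e-8)")
        if not np.allclose(np.diag(values), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal must be 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.dtype != np.int8:
            adj = adj.astype(np.int8)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        n = len(self.node_ids)
        if adj.shape != (n, n):
            raise ValueError(f"adjacency shape {adj.shape} != ({n}, {n})")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(adj).any():
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def edge_list(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(ii, jj)]


def target_edge_count(n_nodes: int, density: float) -> int:
    """Number of edges retained at ``density``, rounded half-up."""
    exact = density * n_nodes * (n_nodes - 1) / 2.0
    return int(np.floor(exact + 0.5))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def binarize_connectome(corr: CorrelationMatrix, density: float) -> BinaryGraph:
    """Threshold a correlation matrix into a connected fixed-density graph.

    A maximum-weight spanning tree on |r| keeps the graph connected; the
    remaining edge budget is filled with the largest |r| pairs not already
    in the tree.  Ties are broken by lexicographic (i, j) node-pair order,
    so the output is deterministic.

    Parameters
    ----------
    corr:
        Labeled symmetric correlation matrix.
    density:
        Fraction of the N(N-1)/2 possible edges to retain, in (0, 1].

    Raises
    ------
    ValueError
        If N < 2, density is out of range, or the rounded edge budget is
        below the N-1 edges a spanning tree requires.
    """
    n = corr.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    m_target = target_edge_count(n, density)
    if m_target < n - 1:
        raise ValueError(
            f"density {density} yields {m_target} edges, below the "
            f"{n - 1} needed for a spanning tree on {n} nodes"
        )

    weights = np.abs(corr.values)
    ii, jj = np.triu_indices(n, 1)
    # sort by descending |r|, then lexicographic (i, j) for determinism
    order = np.lexsort((jj, ii, -weights[ii, jj]))
    edges = list(zip(ii[order], jj[order]))

    adj = np.zeros((n, n), dtype=np.int8)
    uf = _UnionFind(n)
    in_tree: set[tuple[int, int]] = set()
    for i, j in edges:  # Kruskal on descending |r| => maximum spanning tree
        if uf.union(i, j):
            in_tree.add((i, j))
            adj[i, j] = adj[j, i] = 1
            if len(in_tree) == n - 1:
                break

    n_edges = len(in_tree)
    for i, j in edges:
        if n_edges >= m_target:
            break
        if (i, j) not in in_tree and not adj[i, j]:
            adj[i, j] = adj[j, i] = 1
            n_edges += 1

    return BinaryGraph(adj, corr.node_ids)


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """All-pairs shortest-path hop counts; ``np.inf`` marks unreachable pairs."""
    return shortest_path(g.adjacency, method="D", directed=False, unweighted=True)


def graph_from_edges(
    edges: Sequence[tuple[str, str]], node_ids: Sequence[str]
) -> BinaryGraph:
    """Build a :class:`BinaryGraph` from labeled edge pairs."""
    index = {str(n): i for i, n in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=np.int8)
    for a, b in edges:
        i, j = index[str(a)], index[str(b)]
        if i == j:
            raise ValueError(f"self-loop on node {a}")
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj, tuple(node_ids))
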