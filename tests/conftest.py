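"""Shared fixtures: tiny named graphs and random-input factories."""

from __future__ import annotations

import numpy as np
import pytest

from connmap import BinaryGraph, CorrelationMatrix, graph_from_edges


@pytest.fixture
def path3() -> BinaryGraph:
    """Path 1-2-3."""
    return graph_from_edges([("1", "2"), ("2", "3")], ["1", "2", "3"])


@pytest.fixture
def star4() -> BinaryGraph:
    """Star: center c plus three leaves."""
    return graph_from_edges(
        [("c", "l1"), ("c", "l2"), ("c", "l3")], ["c", "l1", "l2", "l3"]
    )


@pytest.fixture
def k4() -> BinaryGraph:
    nodes = ["a", "b", "c", "d"]
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    return graph_from_edges(edges, nodes)


@pytest.fixture
def triangle() -> BinaryGraph:
    return graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")], ["a", "b", "c"])


def random_correlation(n: int, rng: np.random.Generator) -> CorrelationMatrix:
    """Random symmetric correlation-like matrix with unit diagonal."""
    a = rng.uniform(-1.0, 1.0, (n, n))
    r = (a + a.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, [f"n{i}" for i in range(n)])


def random_connected_graph(
    n: int, rng: np.random.Generator, extra_edges: int = 0
) -> BinaryGraph:
    """Random spanning tree plus ``extra_edges`` additional edges."""
    adj = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    for idx in range(1, n):
        i = int(order[idx])
        j = int(rng.choice(order[:idx]))
        adj[i, j] = adj[j, i] = 1
    iu, ju = np.triu_indices(n, 1)
    free = np.flatnonzero(adj[iu, ju] == 0)
    take = min(extra_edges, free.size)
    if take:
        pick = rng.choice(free, size=take, replace=False)
        adj[iu[pick], ju[pick]] = 1
        adj[ju[pick], iu[pick]] = 1
    return BinaryGraph(adj, [f"n{i}" for i in range(n)])
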