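"""Nodal graph metrics: degree, global efficiency, clustering.

Each metric maps a binary graph to one value per node, so a subject is
represented by a length-N vector and a cohort by a subjects x nodes
:class:`MetricMatrix`.

Definitions (for binary undirected graphs):

- degree           D_i     = number of edges at node i
- global efficiency Eglob_i = (1/(N-1)) * sum_{j != i} 1/L_ij, with 1/inf = 0,
  where L_ij is the shortest-path hop count
- clustering       Clust_i = local efficiency of the neighborhood of i: the
  mean inverse shortest-path length over ordered pairs of neighbors of i,
  paths computed inside the neighbor-induced subgraph (node i removed);
  nodes with fewer than two neighbors score 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .graphs import BinaryGraph, shortest_path_lengths

__all__ = [
    "MetricMatrix",
    "degree",
    "global_efficiency",
    "clustering",
    "metric_table",
    "METRICS",
]


@dataclass(frozen=True)
class MetricMatrix:
    """Subjects x nodes table of one nodal metric."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    metric_name: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "subject_ids", tuple(str(s) for s in self.subject_ids)
        )
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        if values.shape != (len(self.subject_ids), len(self.node_ids)):
            raise ValueError(
                f"values shape {values.shape} != "
                f"({len(self.subject_ids)}, {len(self.node_ids)})"
            )
        if not np.isfinite(values).all():
            raise ValueError("metric values must be finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def row(self, subject_id: str) -> np.ndarray:
        return self.values[self.subject_ids.index(str(subject_id))]

    def subset(self, subject_ids: Iterable[str]) -> "MetricMatrix":
        idx = [self.subject_ids.index(str(s)) for s in subject_ids]
        return MetricMatrix(
            self.values[idx],
            tuple(self.subject_ids[i] for i in idx),
            self.node_ids,
            self.metric_name,
        )


def degree(g: BinaryGraph) -> np.ndarray:
    """Edge count per node."""
    return g.adjacency.sum(axis=1).astype(float)


def global_efficiency(g: BinaryGraph) -> np.ndarray:
    """Inverse harmonic mean of shortest-path lengths from each node.

    Unreachable pairs contribute 0 (1/inf := 0), so the value is defined
    even on disconnected graphs.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    lengths = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / lengths
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def clustering(g: BinaryGraph) -> np.ndarray:
    """Local efficiency of each node's neighborhood subgraph."""
    adj = g.adjacency
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nb = np.flatnonzero(adj[i])
        k = nb.size
        if k < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        lengths = shortest_path(sub, method="D", directed=False, unweighted=True)
        with np.errstate(divide="ignore"):
            inv = 1.0 / lengths
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        out[i] = inv.sum() / (k * (k - 1))
    return out


METRICS: dict[str, Callable[[BinaryGraph], np.ndarray]] = {
    "degree": degree,
    "global_efficiency": global_efficiency,
    "clustering": clustering,
}

# short aliases used by the CLI and file schemas
METRIC_ALIASES = {
    "degree": "degree",
    "d": "degree",
    "eglob": "global_efficiency",
    "global_efficiency": "global_efficiency",
    "clust": "clustering",
    "clustering": "clustering",
}


def metric_table(
    graphs: Sequence[BinaryGraph],
    metric_name: str,
    subject_ids: Sequence[str] | None = None,
) -> MetricMatrix:
    """Stack one nodal metric over a cohort of graphs sharing node labels."""
    name = METRIC_ALIASES.get(str(metric_name).lower())
    if name is None:
        raise ValueError(f"unknown metric {metric_name!r}")
    if not graphs:
        raise ValueError("empty graph list")
    node_ids = graphs[0].node_ids
    for g in graphs:
        if g.node_ids != node_ids:
            raise ValueError("graphs do not share node labels")
    if subject_ids is None:
        subject_ids = tuple(f"S{i + 1}" for i in range(len(graphs)))
    fn = METRICS[name]
    values = np.vstack([fn(g) for g in graphs])
    return MetricMatrix(values, tuple(subject_ids), node_ids, name)
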