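"""File schemas: correlation/adjacency CSV, edge lists, metric TSV, scores.

All formats are plain text and round-trip through pandas:

- correlation matrix: square CSV, node labels as header row and first column
- adjacency matrix:   square 0/1 CSV, same labeling
- edge list:          two-column CSV (node_a, node_b)
- metric table:       TSV, first column ``subject``, one column per node
- scores:             CSV (subject, method, score)
- embedding:          CSV (subject, coord_1..coord_d)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .graphs import BinaryGraph, CorrelationMatrix, graph_from_edges
from .features import FeatureScores
from .metrics import MetricMatrix

__all__ = [
    "read_correlation_csv",
    "write_correlation_csv",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_edge_list_csv",
    "write_edge_list_csv",
    "read_metric_tsv",
    "write_metric_tsv",
    "read_scores_csv",
    "write_scores_csv",
    "read_embedding_csv",
    "write_embedding_csv",
    "write_json",
]


def read_correlation_csv(path: str | Path) -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0)
    return CorrelationMatrix(df.to_numpy(dtype=float), tuple(map(str, df.columns)))


def write_correlation_csv(corr: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(corr.values, index=corr.node_ids, columns=corr.node_ids).to_csv(path)


def read_adjacency_csv(path: str | Path) -> BinaryGraph:
    df = pd.read_csv(path, index_col=0)
    return BinaryGraph(df.to_numpy(dtype=int), tuple(map(str, df.columns)))


def write_adjacency_csv(g: BinaryGraph, path: str | Path) -> None:
    pd.DataFrame(g.adjacency, index=g.node_ids, columns=g.node_ids).to_csv(path)


def read_edge_list_csv(path: str | Path, node_ids=None) -> BinaryGraph:
    df = pd.read_csv(path, dtype=str)
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if node_ids is None:
        seen: dict[str, None] = {}
        for a, b in edges:
            seen.setdefault(a)
            seen.setdefault(b)
        node_ids = tuple(seen)
    return graph_from_edges(edges, node_ids)


def write_edge_list_csv(g: BinaryGraph, path: str | Path) -> None:
    pd.DataFrame(g.edge_list(), columns=["node_a", "node_b"]).to_csv(path, index=False)


def read_metric_tsv(path: str | Path, metric_name: str = "metric") -> MetricMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MetricMatrix(
        df.to_numpy(dtype=float),
        tuple(map(str, df.index)),
        tuple(map(str, df.columns)),
        metric_name,
    )


def write_metric_tsv(table: MetricMatrix, path: str | Path) -> None:
    df = pd.DataFrame(table.values, index=table.subject_ids, columns=table.node_ids)
    df.index.name = "subject"
    df.to_csv(path, sep="\t")


def read_scores_csv(path: str | Path) -> FeatureScores:
    df = pd.read_csv(path, dtype={"subject": str})
    methods = df["method"].unique()
    if len(methods) != 1:
        raise ValueError("scores file must hold a single method")
    return FeatureScores(
        str(methods[0]),
        df["score"].to_numpy(dtype=float),
        tuple(df["subject"]),
    )


def write_scores_csv(scores: FeatureScores, path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject": scores.subject_ids,
            "method": scores.method,
            "score": scores.scores,
        }
    ).to_csv(path, index=False)


def read_embedding_csv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(map(str, df.index))


def write_embedding_csv(
    coords: np.ndarray, subject_ids, path: str | Path
) -> None:
    coords = np.asarray(coords, dtype=float)
    cols = [f"coord_{i + 1}" for i in range(coords.shape[1])]
    df = pd.DataFrame(coords, index=list(subject_ids), columns=cols)
    df.index.name = "subject"
    df.to_csv(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
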