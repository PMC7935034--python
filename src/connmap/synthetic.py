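"""Seeded generators of synthetic cohorts with known ground truth.

The clinical fMRI cohorts these methods were designed for are not publicly
deposited, so every pipeline stage is exercised on synthetic data whose
ground truth is known by construction:

- :func:`simulate_metric_cohort` builds nodal-metric vectors directly from
  the hub-disruption regression model: a heavy-tailed reference profile
  h_bar, controls scattered around it, and patient j following
  ``m = h_bar + kappa_j * (h_bar - mean(h_bar)) + noise``.  The disruption
  term is mean-centered so the node average is preserved — the stated
  interpretive assumption of the index — and the intercept-fitted
  regression recovers kappa_j exactly at zero noise.
- :func:`simulate_graph_cohort` builds binary graphs with a fixed edge
  count from a node-attractiveness model; patient attractiveness is blended
  toward its rank-reversed profile by a disruption level beta in [0, 1], so
  hubs progressively swap with non-hubs and the degree-based kappa turns
  negative.
- :func:`make_two_factor_cohort` embeds two latent factors in N dimensions
  through a smooth (optionally curved) map — the recovery fixture for
  covariate-constrained embeddings.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import ReferenceProfile
from .graphs import BinaryGraph
from .metrics import MetricMatrix

__all__ = [
    "SyntheticCohort",
    "GraphCohort",
    "simulate_metric_cohort",
    "simulate_graph_cohort",
    "make_two_factor_cohort",
]


@dataclass(frozen=True)
class SyntheticCohort:
    """Metric-vector cohort with planted hub disruption indices."""

    controls: MetricMatrix
    patients: MetricMatrix
    true_kappa: np.ndarray
    reference: ReferenceProfile
    noise_sigma: float
    seed: int | None

    @property
    def labels(self) -> np.ndarray:
        """0 for controls, 1 for patients, in stacked order."""
        return np.concatenate(
            [np.zeros(self.controls.n_subjects, dtype=int),
             np.ones(self.patients.n_subjects, dtype=int)]
        )

    def stacked(self) -> MetricMatrix:
        return MetricMatrix(
            np.vstack([self.controls.values, self.patients.values]),
            self.controls.subject_ids + self.patients.subject_ids,
            self.controls.node_ids,
            self.controls.metric_name,
        )


def simulate_metric_cohort(
    n_nodes: int,
    n_controls: int,
    n_patients: int,
    kappa_values: float | Sequence[float],
    noise_sigma: float = 0.0,
    seed: int | None = None,
    metric_name: str = "global_efficiency",
) -> SyntheticCohort:
    """Simulate control and patient metric vectors with known kappa.

    The reference profile is a sorted lognormal draw (heavy-tailed hub
    structure).  ``noise_sigma`` is node-wise Gaussian noise expressed as a
    fraction of sd(h_bar).  ``kappa_values`` may be a scalar (shared by all
    patients) or one value per patient.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if n_controls < 1 or n_patients < 0:
        raise ValueError("invalid group sizes")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    kappa = np.asarray(kappa_values, dtype=float)
    if kappa.ndim == 0:
        kappa = np.full(n_patients, float(kappa))
    if kappa.shape != (n_patients,):
        raise ValueError("kappa_values must be scalar or one per patient")
    if not np.isfinite(kappa).all():
        raise ValueError("kappa values must be finite")

    rng = np.random.default_rng(seed)
    h_bar = np.sort(rng.lognormal(mean=0.0, sigma=1.0, size=n_nodes))
    sd = float(np.std(h_bar))
    sigma = noise_sigma * sd

    node_ids = tuple(f"node{i + 1}" for i in range(n_nodes))
    controls = h_bar + rng.normal(0.0, sigma, (n_controls, n_nodes))
    centered = h_bar - h_bar.mean()
    patients = (
        h_bar
        + kappa[:, None] * centered
        + rng.normal(0.0, sigma, (n_patients, n_nodes))
    )
    c_ids = tuple(f"C{i + 1}" for i in range(n_controls))
    p_ids = tuple(f"P{i + 1}" for i in range(n_patients))
    return SyntheticCohort(
        MetricMatrix(controls, c_ids, node_ids, metric_name),
        MetricMatrix(patients, p_ids, node_ids, metric_name),
        kappa,
        ReferenceProfile(h_bar, n_controls, node_ids),
        noise_sigma,
        seed,
    )


@dataclass(frozen=True)
class GraphCohort:
    """Binary-graph cohort with progressive hub reorganization."""

    graphs: tuple[BinaryGraph, ...]
    labels: np.ndarray
    disruption: np.ndarray
    attractiveness: np.ndarray
    seed: int | None

    @property
    def controls(self) -> tuple[BinaryGraph, ...]:
        return tuple(g for g, l in zip(self.graphs, self.labels) if l == 0)

    @property
    def patients(self) -> tuple[BinaryGraph, ...]:
        return tuple(g for g, l in zip(self.graphs, self.labels) if l == 1)


def _sample_graph(
    w: np.ndarray, n_edges: int, rng: np.random.Generator
) -> np.ndarray:
    """Connected graph with exactly n_edges, edge odds ~ w_i * w_j.

    A random spanning tree is grown first (each new node attaches to a
    placed node drawn with probability ~ w), then the remaining budget is
    filled by weighted sampling without replacement over unused pairs.
    """
    n = w.size
    adj = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    placed = [int(order[0])]
    for raw in order[1:]:
        i = int(raw)
        probs = w[placed] / w[placed].sum()
        j = int(rng.choice(placed, p=probs))
        adj[i, j] = adj[j, i] = 1
        placed.append(i)

    iu, ju = np.triu_indices(n, 1)
    free = adj[iu, ju] == 0
    iu, ju = iu[free], ju[free]
    need = n_edges - (n - 1)
    if need > 0:
        pw = w[iu] * w[ju]
        pick = rng.choice(iu.size, size=need, replace=False, p=pw / pw.sum())
        adj[iu[pick], ju[pick]] = 1
        adj[ju[pick], iu[pick]] = 1
    return adj


def simulate_graph_cohort(
    n_nodes: int,
    n_edges: int,
    n_controls: int,
    n_patients: int,
    beta_values: float | Sequence[float],
    seed: int | None = None,
) -> GraphCohort:
    """Simulate a graph cohort whose hub structure degrades with beta.

    Node attractiveness w is a sorted lognormal draw; control graphs use w,
    and patient j uses ``(1 - beta_j) * w + beta_j * reversed(w)`` where
    ``reversed`` assigns each node the attractiveness of its mirror rank.
    At beta = 0 patients are exchangeable with controls; at beta = 1 hubs
    and non-hubs are swapped in expectation.  All graphs share node labels
    and hold exactly ``n_edges`` edges.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not n_nodes - 1 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges must be in [{n_nodes - 1}, {max_edges}], got {n_edges}"
        )
    beta = np.asarray(beta_values, dtype=float)
    if beta.ndim == 0:
        beta = np.full(n_patients, float(beta))
    if beta.shape != (n_patients,):
        raise ValueError("beta_values must be scalar or one per patient")
    if ((beta < 0) | (beta > 1)).any():
        raise ValueError("beta must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    w = np.sort(rng.lognormal(mean=0.0, sigma=1.0, size=n_nodes))
    ranks = np.argsort(np.argsort(w))
    reversed_w = np.sort(w)[::-1][ranks]  # mirror-rank attractiveness
    node_ids = tuple(f"node{i + 1}" for i in range(n_nodes))

    graphs: list[BinaryGraph] = []
    for _ in range(n_controls):
        graphs.append(BinaryGraph(_sample_graph(w, n_edges, rng), node_ids))
    for b in beta:
        wp = (1.0 - b) * w + b * reversed_w
        graphs.append(BinaryGraph(_sample_graph(wp, n_edges, rng), node_ids))
    labels = np.concatenate(
        [np.zeros(n_controls, dtype=int), np.ones(n_patients, dtype=int)]
    )
    return GraphCohort(tuple(graphs), labels, beta, w, seed)


def make_two_factor_cohort(
    n_nodes: int,
    n_subjects: int,
    seed: int | None = None,
    noise_sigma: float = 0.05,
    curvature: float = 0.5,
) -> tuple[MetricMatrix, np.ndarray, np.ndarray]:
    """Features driven by two latent factors through a smooth map.

    Factors f1, f2 are uniform on [-1, 1].  Features are
    ``y = f1 u + f2 v + curvature * g(f1, f2) w + noise`` with orthonormal
    directions u, v, w and the bending term g = (f1^2 - f2^2) / 2; at
    ``curvature=0`` the map is linear and classical embeddings recover the
    factor plane exactly.  ``noise_sigma`` scales i.i.d. Gaussian noise
    relative to the signal's per-coordinate spread.

    Returns the metric table and the two planted factor vectors.
    """
    if n_subjects < 6:
        raise ValueError("need at least 6 subjects")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(-1.0, 1.0, n_subjects)
    f2 = rng.uniform(-1.0, 1.0, n_subjects)
    basis, _ = np.linalg.qr(rng.normal(size=(n_nodes, 3)))
    u, v, w = basis.T
    signal = (
        np.outer(f1, u)
        + np.outer(f2, v)
        + curvature * np.outer((f1**2 - f2**2) / 2.0, w)
    )
    scale = float(np.std(signal))
    values = signal + rng.normal(0.0, noise_sigma * scale, signal.shape)
    table = MetricMatrix(
        values,
        tuple(f"S{i + 1}" for i in range(n_subjects)),
        tuple(f"node{i + 1}" for i in range(n_nodes)),
        "synthetic_two_factor",
    )
    return table, f1, f2
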