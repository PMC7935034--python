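"""Generative mapping from the reduced space back to nodal profiles.

Once a population is embedded (ISOMAP or CCML), a regression f from the
reduced coordinates back to the original metric vectors turns the embedding
into a generative model:

    y_hat = f(x~),    y_i = f(x~_i) + eps_i,

with one regression per node, so f outputs a full length-N profile.  The
regressor is MARS (multivariate adaptive regression splines), degree 1:
an additive expansion in hinge functions max(0, +/-(x_v - t)), grown
greedily in mirrored pairs (forward pass) and pruned by generalized
cross-validation (backward pass).  The result is locally linear and
globally nonlinear, and piecewise-linear predictions make covariate-axis
traversals easy to read.

With a CCML embedding the constrained axis is interpretable, so moving a
subject along it and re-predicting its profile shows how the nodal metric
pattern is expected to change as the covariate (for example the hub
disruption index) degrades or improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .ccml import CcmlEmbedding
from .isomap import EmbeddingResult, _as_matrix
from .metrics import MetricMatrix

__all__ = [
    "MarsModel",
    "GenerativeModel",
    "fit_mars",
    "fit_generative",
    "predict_profile",
    "traverse_covariate",
]


@dataclass(frozen=True)
class MarsModel:
    """Additive hinge expansion fitted by forward selection + GCV pruning.

    ``terms`` lists (variable index, knot, direction) with direction +1
    for max(0, x - t) and -1 for max(0, t - x); ``coefficients[0]`` is the
    intercept and ``coefficients[i + 1]`` multiplies ``terms[i]``.
    """

    terms: tuple[tuple[int, float, int], ...]
    coefficients: np.ndarray
    gcv: float
    residuals: np.ndarray
    penalty: float

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        cols = [np.ones(x.shape[0])]
        for var, knot, direction in self.terms:
            cols.append(np.maximum(0.0, direction * (x[:, var] - knot)))
        return np.column_stack(cols)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.basis(x) @ self.coefficients

    def to_dict(self) -> dict[str, Any]:
        return {
            "terms": [list(t) for t in self.terms],
            "coefficients": self.coefficients.tolist(),
            "gcv": self.gcv,
            "penalty": self.penalty,
        }


def _hinge_pair(x_col: np.ndarray, knot: float) -> tuple[np.ndarray, np.ndarray]:
    return np.maximum(0.0, x_col - knot), np.maximum(0.0, knot - x_col)


def _rss(b: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    coef, _, _, _ = np.linalg.lstsq(b, y, rcond=None)
    resid = y - b @ coef
    return float(resid @ resid), coef


def _gcv(rss: float, n: int, n_terms: int, n_knots: int, penalty: float) -> float:
    c = n_terms + penalty * n_knots
    if c >= n:
        return np.inf
    return rss / n / (1.0 - c / n) ** 2


def fit_mars(
    x: np.ndarray,
    y: np.ndarray,
    max_terms: int | None = None,
    penalty: float = 3.0,
) -> MarsModel:
    """Fit a degree-1 MARS model of y on the columns of x.

    Forward pass: starting from the intercept, repeatedly add the mirrored
    hinge pair (at an observed data value of one variable) that most
    reduces the residual sum of squares, until ``max_terms`` basis
    functions are reached or the fit stops improving.  Backward pass:
    greedily delete single terms, keeping the model with the lowest
    generalized cross-validation score GCV = RSS/n / (1 - C/n)^2 with
    effective parameters C = (#terms incl. intercept) + penalty * #knots.

    ``max_terms`` defaults to min(21, n - 1).  Deterministic: knot
    candidates are scanned in sorted order and ties keep the first.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim != 2:
        raise ValueError("x must be 2-D (n_samples, n_features)")
    y = np.asarray(y, dtype=float).ravel()
    n, d = x.shape
    if y.shape != (n,):
        raise ValueError("x and y sample counts differ")
    if n < 4:
        raise ValueError("MARS needs at least 4 samples")
    if max_terms is None:
        max_terms = min(21, n - 1)

    terms: list[tuple[int, float, int]] = []
    basis = np.ones((n, 1))
    rss, coef = _rss(basis, y)
    y_scale = max(float(np.var(y)) * n, 1.0)

    # ---- forward pass: add mirrored hinge pairs -------------------------
    while len(terms) + 3 <= max_terms + 1:  # +1 for the intercept column
        best = None  # (rss, var, knot, b_plus, b_minus)
        for var in range(d):
            for knot in np.unique(x[:, var])[:-1]:  # hinge at max is all-zero
                bp, bm = _hinge_pair(x[:, var], knot)
                cand = np.column_stack([basis, bp, bm])
                r, _ = _rss(cand, y)
                if best is None or r < best[0] - 1e-15:
                    best = (r, var, float(knot), bp, bm)
        if best is None or best[0] > rss - 1e-12 * y_scale:
            break
        rss = best[0]
        terms.append((best[1], best[2], +1))
        terms.append((best[1], best[2], -1))
        basis = np.column_stack([basis, best[3], best[4]])
        if rss <= 1e-24 * y_scale:
            break

    def knots_of(sub: list[tuple[int, float, int]]) -> int:
        return len({(v, t) for v, t, _ in sub})

    # ---- backward pass: greedy single-term deletion by GCV --------------
    current = list(terms)
    cur_basis = basis
    cur_rss = rss
    best_terms = list(current)
    best_gcv = _gcv(cur_rss, n, len(current) + 1, knots_of(current), penalty)
    while current:
        trial = None  # (gcv, rss, pos, basis)
        for pos in range(len(current)):
            keep = [c for c in range(cur_basis.shape[1]) if c != pos + 1]
            b = cur_basis[:, keep]
            r, _ = _rss(b, y)
            sub = current[:pos] + current[pos + 1 :]
            g = _gcv(r, n, len(sub) + 1, knots_of(sub), penalty)
            if trial is None or g < trial[0]:
                trial = (g, r, pos, b)
        g, r, pos, b = trial
        current = current[:pos] + current[pos + 1 :]
        cur_basis, cur_rss = b, r
        if g < best_gcv:
            best_gcv, best_terms = g, list(current)

    model_basis = np.column_stack(
        [np.ones(n)]
        + [np.maximum(0.0, s * (x[:, v] - t)) for v, t, s in best_terms]
    )
    final_rss, final_coef = _rss(model_basis, y)
    residuals = y - model_basis @ final_coef
    gcv = _gcv(final_rss, n, len(best_terms) + 1, knots_of(best_terms), penalty)
    return MarsModel(tuple(best_terms), final_coef, gcv, residuals, penalty)


@dataclass(frozen=True)
class GenerativeModel:
    """One MARS model per node: maps reduced coordinates to a profile."""

    models: tuple[MarsModel, ...]
    residual_matrix: np.ndarray
    node_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    n_dims: int

    @property
    def n_nodes(self) -> int:
        return len(self.models)

    def per_node_rmse(self) -> np.ndarray:
        return np.sqrt(np.mean(self.residual_matrix**2, axis=0))

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_dims": self.n_dims,
            "node_ids": list(self.node_ids),
            "models": [m.to_dict() for m in self.models],
        }


def _embedding_coords(emb: Any) -> np.ndarray:
    if isinstance(emb, (EmbeddingResult, CcmlEmbedding)):
        return emb.coords
    return np.asarray(emb, dtype=float)


def fit_generative(
    emb: Any,
    features: MetricMatrix | np.ndarray,
    max_terms: int | None = None,
    penalty: float = 3.0,
) -> GenerativeModel:
    """Fit coordinate-wise MARS from an embedding to the metric table."""
    coords = _embedding_coords(emb)
    y = _as_matrix(features)
    if coords.shape[0] != y.shape[0]:
        raise ValueError("embedding and features cover different subject counts")
    if isinstance(features, MetricMatrix):
        node_ids = features.node_ids
        subject_ids = features.subject_ids
    else:
        node_ids = tuple(f"node{i + 1}" for i in range(y.shape[1]))
        subject_ids = tuple(f"S{i + 1}" for i in range(y.shape[0]))
    models = tuple(
        fit_mars(coords, y[:, j], max_terms=max_terms, penalty=penalty)
        for j in range(y.shape[1])
    )
    residuals = np.column_stack([m.residuals for m in models])
    return GenerativeModel(models, residuals, node_ids, subject_ids, coords.shape[1])


def predict_profile(model: GenerativeModel, point: np.ndarray) -> np.ndarray:
    """Evaluate the generative map at one reduced-space point."""
    p = np.asarray(point, dtype=float).ravel()
    if p.size != model.n_dims:
        raise ValueError(
            f"point has {p.size} coordinates, model expects {model.n_dims}"
        )
    return np.array([m.predict(p[None, :])[0] for m in model.models])


def traverse_covariate(
    model: GenerativeModel,
    emb: CcmlEmbedding,
    subject_id: str,
    covariate_values: Sequence[float],
) -> list[np.ndarray]:
    """Predict a subject's profile at alternative covariate values.

    The subject's free coordinates are held fixed while the constrained
    axis is set to ``alpha * value`` for each requested value, tracing how
    the nodal profile is expected to change along the covariate direction.
    """
    if str(subject_id) not in emb.subject_ids:
        raise KeyError(f"unknown subject {subject_id!r}")
    idx = emb.subject_ids.index(str(subject_id))
    free = emb.free_coords[idx]
    out = []
    for value in covariate_values:
        point = np.concatenate([[emb.alpha * float(value)], free])
        out.append(predict_profile(model, point))
    return out
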