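"""ISOMAP embedding of subject metric vectors and reduced-space regression.

Subjects are points in R^N (one coordinate per node).  ISOMAP approximates
distances along the data manifold by shortest paths on a k-nearest-neighbor
graph whose edges carry Euclidean lengths, then embeds those geodesic
distances with classical multidimensional scaling.  With the neighbor graph
complete the procedure reduces to PCA.

On the reduced coordinates the module also provides:

- radial-basis-function interpolation of a scalar covariate, with a
  leave-one-out error summary (RMSE and maximum error),
- an L2-regularized logistic probability map for two-group membership,
- a leave-one-out RBF-SVM classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .metrics import MetricMatrix

__all__ = [
    "EmbeddingResult",
    "CovariateSurface",
    "ClassProbabilityMap",
    "geodesic_distances",
    "isomap_embed",
    "fit_covariate_surface",
    "loo_covariate_error",
    "class_probability_map",
    "svm_accuracy",
]


def _as_matrix(features: Any) -> np.ndarray:
    if isinstance(features, MetricMatrix):
        return features.values
    return np.asarray(features, dtype=float)


@dataclass(frozen=True)
class EmbeddingResult:
    """Reduced coordinates from classical MDS on geodesic distances."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    residual_variance: float
    k: int

    @property
    def n_subjects(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def geodesic_distances(
    x: np.ndarray, k: int = 4, bridge_components: bool = True
) -> np.ndarray:
    """Shortest-path distances on the symmetrized kNN graph of ``x``.

    The neighbor relation is the union of directed k-nearest links, with
    Euclidean edge weights.  A disconnected neighbor graph is repaired by
    repeatedly adding the shortest Euclidean edge between two components
    (or raises if ``bridge_components`` is false).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1)
    d = squareform(pdist(x))
    w = np.zeros_like(d)
    order = np.argsort(d, axis=1, kind="stable")
    for i in range(n):
        for j in order[i, 1 : k + 1]:  # skip self at position 0
            w[i, j] = w[j, i] = d[i, j]

    n_comp, labels = connected_components(w > 0, directed=False)
    # isolated duplicate points (distance 0 to their neighbors) count as linked
    while n_comp > 1:
        if not bridge_components:
            raise ValueError(
                f"kNN graph has {n_comp} components; increase k or enable bridging"
            )
        best = (np.inf, -1, -1)
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] != labels[j] and d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        _, i, j = best
        w[i, j] = w[j, i] = max(d[i, j], np.finfo(float).tiny)
        n_comp, labels = connected_components(w > 0, directed=False)

    geo = shortest_path(w, method="D", directed=False)
    # duplicate points give zero-weight edges that csgraph drops; patch them
    if not np.isfinite(geo).all():
        dup = ~np.isfinite(geo)
        geo[dup] = d[dup]
    return geo


def _classical_mds(dist: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:d], 0.0, None)
    coords = evecs[:, :d] * np.sqrt(lam)
    # deterministic sign: largest-|coordinate| entry positive per axis
    for a in range(coords.shape[1]):
        col = coords[:, a]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            coords[:, a] = -col
    return coords, evals


def isomap_embed(
    features: MetricMatrix | np.ndarray,
    k: int = 4,
    d: int = 2,
    bridge_components: bool = True,
) -> EmbeddingResult:
    """Embed subjects in ``d`` dimensions by ISOMAP.

    ``k`` defaults to 4 neighbors, suited to cohorts of a few dozen
    subjects.  Coordinates are column-centered; the per-axis sign is fixed
    deterministically.  ``residual_variance`` is ``1 - r^2`` between
    geodesic and embedded pairwise distances.
    """
    x = _as_matrix(features)
    n = x.shape[0]
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} subjects for a {d}-D embedding")
    geo = geodesic_distances(x, k=k, bridge_components=bridge_components)
    coords, evals = _classical_mds(geo, d)
    emb_d = squareform(pdist(coords))
    iu = np.triu_indices(n, 1)
    g, e = geo[iu], emb_d[iu]
    if np.std(g) > 0 and np.std(e) > 0:
        r = float(np.corrcoef(g, e)[0, 1])
        resid = 1.0 - r**2
    else:
        resid = 0.0
    return EmbeddingResult(coords, evals, resid, k)


@dataclass(frozen=True)
class CovariateSurface:
    """RBF interpolant of a covariate over the reduced space."""

    kernel: str
    centers: np.ndarray
    values: np.ndarray
    _interp: RBFInterpolator

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return self._interp(p)


def fit_covariate_surface(
    emb: EmbeddingResult | np.ndarray,
    covariate: np.ndarray,
    kernel: str = "thin_plate_spline",
) -> CovariateSurface:
    """Interpolate a covariate exactly through the embedded points.

    Default kernel is the thin-plate spline (reproduces affine covariates
    exactly); ``kernel="gaussian"`` uses the median inter-point distance as
    the kernel width.
    """
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    c = np.asarray(covariate, dtype=float)
    if c.shape != (coords.shape[0],):
        raise ValueError("one covariate value per embedded subject required")
    kwargs: dict[str, Any] = {"kernel": kernel, "smoothing": 0.0}
    if kernel == "gaussian":
        med = float(np.median(pdist(coords)))
        if med <= 0:
            raise ValueError("degenerate embedding: zero median distance")
        kwargs["epsilon"] = 1.0 / med
    interp = RBFInterpolator(coords, c, **kwargs)
    return CovariateSurface(kernel, coords, c, interp)


def loo_covariate_error(
    emb: EmbeddingResult | np.ndarray,
    covariate: np.ndarray,
    kernel: str = "thin_plate_spline",
) -> tuple[float, float]:
    """Leave-one-out (RMSE, max |error|) of the covariate surface."""
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    c = np.asarray(covariate, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    errors = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        surf = fit_covariate_surface(coords[mask], c[mask], kernel=kernel)
        errors[i] = surf(coords[i : i + 1])[0] - c[i]
    rmse = float(np.sqrt(np.mean(errors**2)))
    return rmse, float(np.max(np.abs(errors)))


@dataclass(frozen=True)
class ClassProbabilityMap:
    """Logistic model of class membership over the reduced space."""

    coefficients: np.ndarray
    intercept: float
    probabilities: np.ndarray
    classes: tuple[Any, Any]
    _model: LogisticRegression

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return self._model.predict_proba(p)[:, 1]


def class_probability_map(
    emb: EmbeddingResult | np.ndarray, labels: np.ndarray, c: float = 1.0
) -> ClassProbabilityMap:
    """L2-regularized logistic regression on the reduced coordinates."""
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    model = LogisticRegression(C=c)
    model.fit(coords, lab)
    prob = model.predict_proba(coords)[:, 1]
    return ClassProbabilityMap(
        model.coef_[0].copy(),
        float(model.intercept_[0]),
        prob,
        (classes[0], classes[1]),
        model,
    )


def svm_accuracy(
    coords: np.ndarray, labels: np.ndarray, c: float = 1.0
) -> float:
    """Leave-one-out accuracy of an RBF-kernel SVM in the reduced space.

    The kernel width follows the median heuristic,
    ``gamma = 1 / (2 median(d)^2)`` over nonzero pairwise distances;
    cost C = 1.  Deterministic: no random state enters the fit.
    """
    if hasattr(coords, "coords"):
        coords = coords.coords
    x = np.asarray(coords, dtype=float)
    lab = np.asarray(labels)
    classes, counts = np.unique(lab, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("two classes with at least 2 members each required")
    dists = pdist(x)
    nz = dists[dists > 0]
    med = float(np.median(nz)) if nz.size else 1.0
    gamma = 1.0 / (2.0 * med**2)
    n = x.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(lab[mask]).size < 2:
            continue
        model = SVC(C=c, kernel="rbf", gamma=gamma)
        model.fit(x[mask], lab[mask])
        correct += int(model.predict(x[i : i + 1])[0] == lab[i])
    return correct / n
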