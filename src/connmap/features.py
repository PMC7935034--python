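"""Scalar per-subject descriptors of nodal metric profiles.

Four ways to collapse a subject's length-N metric vector to one scalar:

- ``kappa`` — the hub disruption index: the slope of the regression of
  (subject - reference) on the reference profile, where the reference is
  the node-wise control-group mean.  kappa = 0 means the subject shares the
  reference's hub organization; kappa < 0 means reference hubs are no
  longer hubs (and vice versa).
- ``mean`` — the node average, a global network property blind to which
  nodes carry the hubs.
- ``lda``  — projection on the Fisher discriminant direction separating the
  two groups (shrinkage-regularized for the high-dimension low-sample-size
  regime).
- ``fs``   — univariate feature selection: the single node whose two-sample
  t statistic best separates the groups.

Group differences in any of these scores are assessed with a seeded
permutation test on the difference of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import numpy as np
from scipy import stats

from .metrics import MetricMatrix

__all__ = [
    "ReferenceProfile",
    "KappaFit",
    "FeatureScores",
    "PermutationResult",
    "reference_profile",
    "hub_disruption_index",
    "kappa_scores",
    "mean_score",
    "mean_scores",
    "lda_scores",
    "fs_scores",
    "permutation_test",
    "correlate_scores",
]


@dataclass(frozen=True)
class ReferenceProfile:
    """Node-wise mean metric over the control group."""

    h_bar: np.ndarray
    group_size: int
    node_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        h = np.asarray(self.h_bar, dtype=float)
        object.__setattr__(self, "h_bar", h)
        if h.ndim != 1 or not np.isfinite(h).all():
            raise ValueError("reference profile must be a finite 1-D vector")

    @property
    def variance(self) -> float:
        return float(np.var(self.h_bar))


@dataclass(frozen=True)
class KappaFit:
    """Least-squares fit of (subject - reference) on the reference."""

    kappa: float
    intercept: float
    residuals: np.ndarray
    stderr_kappa: float
    r_squared: float


@dataclass(frozen=True)
class FeatureScores:
    """One scalar per subject plus method-specific diagnostics."""

    method: str
    scores: np.ndarray
    subject_ids: tuple[str, ...]
    detail: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.shape != (len(self.subject_ids),):
            raise ValueError("one score per subject required")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    n_permutations: int
    p_value: float
    seed: int | None
    exhaustive: bool = False


def reference_profile(controls: MetricMatrix) -> ReferenceProfile:
    """Average the control rows node-wise."""
    if controls.n_subjects < 1:
        raise ValueError("empty control group")
    return ReferenceProfile(
        controls.values.mean(axis=0), controls.n_subjects, controls.node_ids
    )


def hub_disruption_index(
    subject: np.ndarray, ref: ReferenceProfile, fit_intercept: bool = True
) -> KappaFit:
    """Fit the hub disruption index kappa for one subject.

    Ordinary least squares of ``subject - h_bar`` on ``h_bar``.  An
    intercept is fitted by default; with ``fit_intercept=False`` the line
    is forced through the origin, the literal reading of the defining
    regression, which assumes the two groups share the same global mean.
    """
    m = np.asarray(subject, dtype=float)
    h = ref.h_bar
    if m.shape != h.shape:
        raise ValueError(f"length mismatch: subject {m.shape}, reference {h.shape}")
    if ref.variance <= 0:
        raise ValueError("constant reference profile: slope undefined")
    y = m - h
    n = h.size
    if fit_intercept:
        res = stats.linregress(h, y)
        slope, intercept = float(res.slope), float(res.intercept)
        stderr = float(res.stderr)
        r2 = float(res.rvalue) ** 2
        resid = y - (slope * h + intercept)
    else:
        sxx = float(h @ h)
        slope = float(h @ y) / sxx
        intercept = 0.0
        resid = y - slope * h
        dof = max(n - 1, 1)
        stderr = math.sqrt(float(resid @ resid) / dof / sxx)
        ss_tot = float(y @ y)  # uncentered: no intercept in the model
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return KappaFit(slope, intercept, resid, stderr, r2)


def kappa_scores(
    features: MetricMatrix, ref: ReferenceProfile, fit_intercept: bool = True
) -> FeatureScores:
    """Hub disruption index of every subject against a fixed reference."""
    scores = np.array(
        [
            hub_disruption_index(row, ref, fit_intercept=fit_intercept).kappa
            for row in features.values
        ]
    )
    return FeatureScores("kappa", scores, features.subject_ids)


def mean_score(subject: np.ndarray) -> float:
    """Node average of one subject's metric vector."""
    m = np.asarray(subject, dtype=float)
    if m.size == 0:
        raise ValueError("empty metric vector")
    return float(m.mean())


def mean_scores(features: MetricMatrix) -> FeatureScores:
    return FeatureScores(
        "mean", features.values.mean(axis=1), features.subject_ids
    )


def _split_labels(labels: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    if lab.shape != (n,):
        raise ValueError("one label per subject required")
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    return lab == classes[0], lab == classes[1]


def lda_scores(
    features: MetricMatrix, labels: np.ndarray, shrinkage: float = 0.1
) -> FeatureScores:
    """Project subjects on the (regularized) Fisher discriminant direction.

    The within-class scatter is shrunk toward its diagonal,
    ``S = (1 - lambda) S_w + lambda diag(S_w)``, so the direction stays
    defined when nodes outnumber subjects.  Scores are centered on the
    grand mean.
    """
    X = features.values
    mask0, mask1 = _split_labels(labels, features.n_subjects)
    if features.n_subjects < 3:
        raise ValueError("LDA needs at least 3 subjects")
    mu0, mu1 = X[mask0].mean(axis=0), X[mask1].mean(axis=0)
    diff = mu1 - mu0
    if not np.any(diff):
        raise ValueError("identical class means: discriminant undefined")
    xc = np.vstack([X[mask0] - mu0, X[mask1] - mu1])
    sw = xc.T @ xc / max(features.n_subjects - 2, 1)
    s = (1.0 - shrinkage) * sw + shrinkage * np.diag(np.diag(sw))
    # guard against exactly zero-variance nodes
    ridge = 1e-12 * max(float(np.trace(s)) / s.shape[0], 1.0)
    s[np.diag_indices_from(s)] += ridge
    w = np.linalg.solve(s, diff)
    scores = (X - X.mean(axis=0)) @ w
    return FeatureScores(
        "lda", scores, features.subject_ids, {"weights": w, "shrinkage": shrinkage}
    )


def fs_scores(features: MetricMatrix, labels: np.ndarray) -> FeatureScores:
    """Select the single node with the largest |two-sample t| statistic.

    Zero-variance nodes get t = 0; ties resolve to the lowest node index.
    """
    X = features.values
    mask0, mask1 = _split_labels(labels, features.n_subjects)
    n0, n1 = int(mask0.sum()), int(mask1.sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 subjects")
    mu0, mu1 = X[mask0].mean(axis=0), X[mask1].mean(axis=0)
    v0 = X[mask0].var(axis=0, ddof=1)
    v1 = X[mask1].var(axis=0, ddof=1)
    pooled = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    se = np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mu1 - mu0) / se, 0.0)
    best = int(np.argmax(np.abs(t)))  # argmax returns the first (lowest) index
    return FeatureScores(
        "fs",
        X[:, best],
        features.subject_ids,
        {
            "node_index": best,
            "node_id": features.node_ids[best],
            "t_statistic": float(t[best]),
            "t_statistics": t,
        },
    )


def permutation_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test on the difference of group means.

    The labels are shuffled ``n_permutations`` times (Monte Carlo, seeded);
    when the number of distinct label assignments is no larger than the
    requested count, all assignments are enumerated instead.  The Monte
    Carlo p-value uses the add-one estimator (b + 1) / (B + 1), so the
    smallest attainable p is 1 / (B + 1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    tol = 1e-12 * max(1.0, abs(observed))

    n_distinct = math.comb(n, na)
    if n_distinct <= n_permutations:
        count = 0
        idx = np.arange(n)
        for combo in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            diff = pooled[mask].mean() - pooled[~mask].mean()
            if abs(diff) >= abs(observed) - tol:
                count += 1
        return PermutationResult(
            observed, n_distinct, count / n_distinct, seed, exhaustive=True
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = perm[:na].mean() - perm[na:].mean()
        if abs(diff) >= abs(observed) - tol:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(observed, n_permutations, p, seed, exhaustive=False)


def correlate_scores(a: FeatureScores, b: FeatureScores) -> float:
    """Pearson correlation between two score vectors over the same subjects."""
    if a.subject_ids != b.subject_ids:
        raise ValueError("scores cover different subjects (or different order)")
    if np.std(a.scores) == 0 or np.std(b.scores) == 0:
        raise ValueError("zero variance in a score vector")
    r, _ = stats.pearsonr(a.scores, b.scores)
    return float(r)
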