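"""Covariate-constrained manifold learning (CCML).

Classical manifold learning leaves the reduced coordinates uninterpreted.
CCML fixes that by pinning one reduced axis to a covariate chosen by the
investigator (for example the hub disruption index): subject i is embedded
at ``x~_i = [alpha * c_i, x_i]`` where ``c_i`` is its covariate value,
``alpha`` a global scale balancing the axes, and ``x_i`` free coordinates.
Only ``alpha`` and the free coordinates are optimized; the constrained axis
is scaled covariate values by construction, never approximated.

The fit minimizes the raw stress

    E = sum_{i<j} ( ||x~_i - x~_j|| - ||y_i - y_j|| )^2

between reduced and original (Euclidean) pairwise distances.  Points are
inserted one at a time, farthest-first by geodesic distance (the same
k-neighbor geodesics ISOMAP uses), starting from the two mutually farthest
subjects; each insertion triggers three optimizations of E — over the new
point's free coordinates, over alpha, and over the free coordinates of the
points already placed.  A final joint refinement polishes all free
coordinates and alpha together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .isomap import geodesic_distances, _as_matrix
from .metrics import MetricMatrix

__all__ = ["CcmlEmbedding", "ccml_cost", "ccml_embed"]


def _pair_stress(
    points: np.ndarray, target: np.ndarray, squared_differences: bool
) -> float:
    dd = pdist(points)
    if squared_differences:
        return float(np.sum((dd**2 - target**2) ** 2))
    return float(np.sum((dd - target) ** 2))


def _stress_gradient(
    points: np.ndarray, target_sq: np.ndarray, squared_differences: bool
) -> np.ndarray:
    """dE/dpoints for the stress; ``target_sq`` is the square-form target."""
    m = points.shape[0]
    d = squareform(pdist(points))
    diff = points[:, None, :] - points[None, :, :]
    if squared_differences:
        w = 4.0 * (d**2 - target_sq**2)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(d > 0, 2.0 * (d - target_sq) / d, 0.0)
    np.fill_diagonal(w, 0.0)
    return (w[:, :, None] * diff).sum(axis=1)


def ccml_cost(
    reduced: np.ndarray,
    original: np.ndarray,
    squared_differences: bool = False,
) -> float:
    """Stress between reduced-space and original-space pairwise distances.

    ``reduced`` must already carry the scaled covariate in its first
    column.  Zero iff every pairwise distance is reproduced.
    """
    r = np.asarray(reduced, dtype=float)
    y = np.asarray(original, dtype=float)
    if r.shape[0] != y.shape[0]:
        raise ValueError("reduced and original point counts differ")
    return _pair_stress(r, pdist(y), squared_differences)


@dataclass(frozen=True)
class CcmlEmbedding:
    """Result of a CCML fit.

    ``coords[:, 0]`` equals ``alpha * covariate`` exactly;
    ``free_coords`` holds the remaining d-1 optimized columns.
    ``cost_trace`` records, per insertion, the stress after initialization
    and after each of the three sub-optimizations.
    """

    free_coords: np.ndarray
    alpha: float
    covariate: np.ndarray
    cost: float
    insertion_order: tuple[int, ...]
    cost_trace: tuple[dict[str, Any], ...]
    subject_ids: tuple[str, ...]
    convergence_fraction: float | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.alpha * self.covariate, self.free_coords])

    @property
    def n_subjects(self) -> int:
        return self.covariate.size

    @property
    def n_dims(self) -> int:
        return 1 + self.free_coords.shape[1]


class _State:
    """Mutable optimization state: alpha plus per-subject free coordinates."""

    def __init__(self, n: int, d_free: int, covariate: np.ndarray, alpha: float):
        self.free = np.zeros((n, d_free))
        self.alpha = alpha
        self.cov = covariate
        self.d_free = d_free

    def points(self, idx: Sequence[int]) -> np.ndarray:
        idx = list(idx)
        return np.column_stack(
            [self.alpha * self.cov[idx], self.free[idx]]
        )


def _cost_subset(
    state: _State, idx: list[int], target: np.ndarray, squared: bool
) -> float:
    if len(idx) < 2:
        return 0.0
    return _pair_stress(state.points(idx), target, squared)


def ccml_embed(
    features: MetricMatrix | np.ndarray,
    covariate: np.ndarray,
    d: int = 2,
    *,
    k: int = 4,
    squared_differences: bool = False,
    inner_loops: int = 1,
    joint_previous: bool = True,
    polish: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
    restarts: int = 0,
    seed: int | None = None,
    subject_ids: Sequence[str] | None = None,
) -> CcmlEmbedding:
    """Embed subjects with the first reduced axis pinned to a covariate.

    Parameters
    ----------
    features:
        Subjects x nodes metric table (or plain array); rows are the
        original-space vectors whose Euclidean distances the embedding
        reproduces.
    covariate:
        One scalar per subject; must not be constant (alpha would be
        unidentifiable).
    d:
        Total reduced dimension including the constrained axis (default 2,
        i.e. one free coordinate).
    k:
        Neighbor count for the geodesic distances that drive the
        farthest-first insertion order.
    inner_loops:
        Number of passes over the three sub-optimizations per insertion.
    joint_previous:
        Re-optimize already-inserted free coordinates jointly (default) or
        one point at a time.
    polish:
        Finish with a joint refinement of alpha and all free coordinates.
    restarts:
        If > 0, rerun the insertion loop ``restarts`` times from random
        initial placements (seeded) and report the fraction of runs landing
        in the best cost basin as ``convergence_fraction``.

    Deterministic given (options, seed).
    """
    x = _as_matrix(features)
    c = np.asarray(covariate, dtype=float)
    n = x.shape[0]
    if c.shape != (n,):
        raise ValueError("one covariate value per subject required")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if d < 1:
        raise ValueError("d must be >= 1")
    if np.ptp(c) == 0:
        raise ValueError("constant covariate: scale factor unidentifiable")
    if isinstance(features, MetricMatrix) and subject_ids is None:
        subject_ids = features.subject_ids
    if subject_ids is None:
        subject_ids = tuple(f"S{i + 1}" for i in range(n))

    d_orig = squareform(pdist(x))
    geo = geodesic_distances(x, k=k)

    def run(init_rng: np.random.Generator | None) -> tuple[_State, list, list]:
        return _insertion_loop(
            x,
            c,
            d,
            d_orig,
            geo,
            squared_differences,
            inner_loops,
            joint_previous,
            max_iter,
            tol,
            init_rng,
        )

    state, order, trace = run(None)
    if polish:
        trace.append(
            _polish(state, list(range(n)), d_orig, squared_differences, max_iter, tol)
        )

    convergence_fraction: float | None = None
    if restarts > 0:
        rng = np.random.default_rng(seed)
        costs = []
        for _ in range(restarts):
            s_r, _, _ = run(rng)
            if polish:
                _polish(s_r, list(range(n)), d_orig, squared_differences, max_iter, tol)
            costs.append(
                _pair_stress(s_r.points(list(range(n))), pdist(x), squared_differences)
            )
        costs = np.array(costs)
        best = costs.min()
        band = max(1e-6 * max(best, 1.0), 1e-9)
        convergence_fraction = float(np.mean(costs <= best + band))

    final_cost = _pair_stress(
        state.points(list(range(n))), pdist(x), squared_differences
    )
    return CcmlEmbedding(
        state.free.copy(),
        float(state.alpha),
        c.copy(),
        final_cost,
        tuple(order),
        tuple(trace),
        tuple(subject_ids),
        convergence_fraction,
    )


def _insertion_loop(
    x: np.ndarray,
    c: np.ndarray,
    d: int,
    d_orig: np.ndarray,
    geo: np.ndarray,
    squared: bool,
    inner_loops: int,
    joint_previous: bool,
    max_iter: int,
    tol: float,
    init_rng: np.random.Generator | None,
) -> tuple[_State, list[int], list[dict[str, Any]]]:
    n = x.shape[0]
    d_free = d - 1

    # landmark pair: largest geodesic distance, lexicographic tie-break
    iu = np.triu_indices(n, 1)
    flat = geo[iu]
    best = int(np.argmax(flat))  # argmax picks first max => lexicographic
    a, b = int(iu[0][best]), int(iu[1][best])

    # initial scale: spread of data distances over spread of covariate
    alpha0 = float(d_orig.max() / np.ptp(c))
    state = _State(n, d_free, c, alpha0)

    # place the pair so their reduced distance matches the original one
    if d_free > 0:
        gap2 = d_orig[a, b] ** 2 - (alpha0 * (c[a] - c[b])) ** 2
        state.free[b, 0] = np.sqrt(max(gap2, 0.0))
        if init_rng is not None:
            scale = max(d_orig.max(), 1.0)
            state.free[[a, b]] += init_rng.normal(0, 0.1 * scale, (2, d_free))

    inserted = [a, b]
    trace: list[dict[str, Any]] = []

    remaining = [i for i in range(n) if i not in (a, b)]
    # the landmark pair gets one alpha refinement before insertions start
    t0 = _cost_subset(state, inserted, _sub_target(d_orig, inserted), squared)
    t1 = _optimize_alpha(state, inserted, d_orig, squared, max_iter, tol)
    trace.append({"stage": "init_pair", "subjects": (a, b), "costs": (t0, t1)})

    while remaining:
        # farthest-point choice: max over remaining of min geodesic to inserted
        minimum = np.array([geo[r, inserted].min() for r in remaining])
        nxt = remaining.pop(int(np.argmax(minimum)))

        # initialize at the inverse-distance barycenter of 3 nearest placed
        if d_free > 0:
            near = sorted(inserted, key=lambda j: (d_orig[nxt, j], j))[:3]
            wts = 1.0 / (d_orig[nxt, near] + 1e-12)
            state.free[nxt] = (wts[:, None] * state.free[near]).sum(0) / wts.sum()
            if init_rng is not None:
                scale = max(d_orig.max(), 1.0)
                state.free[nxt] += init_rng.normal(0, 0.1 * scale, d_free)

        inserted.append(nxt)
        target = _sub_target(d_orig, inserted)
        costs = [_cost_subset(state, inserted, target, squared)]
        for _ in range(max(inner_loops, 1)):
            costs.append(
                _optimize_new_point(
                    state, inserted, nxt, target, squared, max_iter, tol, d_orig
                )
            )
            costs.append(_optimize_alpha(state, inserted, d_orig, squared, max_iter, tol))
            costs.append(
                _optimize_previous(
                    state,
                    inserted,
                    nxt,
                    target,
                    squared,
                    joint_previous,
                    max_iter,
                    tol,
                )
            )
        trace.append({"stage": "insert", "subject": nxt, "costs": tuple(costs)})

    return state, inserted, trace


def _sub_target(d_orig: np.ndarray, idx: list[int]) -> np.ndarray:
    sub = d_orig[np.ix_(idx, idx)]
    return sub[np.triu_indices(len(idx), 1)]


def _point_starts(
    state: _State, inserted: list[int], nxt: int, d_orig: np.ndarray | None
) -> list[np.ndarray]:
    """Deterministic multi-start candidates for one point's free coords.

    The stress in a single point is multimodal (mirror basins on the free
    axis), so besides the current placement we try the reflection across
    the other points' centroid and, when original distances are supplied,
    the two triangulation solutions implied by the distance to the nearest
    placed point: free = free_j +/- sqrt(d_ij^2 - (alpha dc)^2).
    """
    starts = [state.free[nxt].copy()]
    others = [i for i in inserted if i != nxt]
    if others:
        centroid = state.free[others].mean(axis=0)
        starts.append(2.0 * centroid - state.free[nxt])
        if d_orig is not None:
            j = min(others, key=lambda o: (d_orig[nxt, o], o))
            gap2 = d_orig[nxt, j] ** 2 - (
                state.alpha * (state.cov[nxt] - state.cov[j])
            ) ** 2
            if gap2 > 0:
                offset = np.zeros(state.d_free)
                offset[0] = np.sqrt(gap2)
                starts.append(state.free[j] + offset)
                starts.append(state.free[j] - offset)
    return starts


def _optimize_new_point(
    state: _State,
    inserted: list[int],
    nxt: int,
    target: np.ndarray,
    squared: bool,
    max_iter: int,
    tol: float,
    d_orig: np.ndarray | None = None,
) -> float:
    if state.d_free == 0:
        return _cost_subset(state, inserted, target, squared)

    def fun(v: np.ndarray) -> float:
        state.free[nxt] = v
        return _cost_subset(state, inserted, target, squared)

    x0 = state.free[nxt].copy()
    best_f, best_x = fun(x0), x0
    for start in _point_starts(state, inserted, nxt, d_orig):
        res = minimize(
            fun,
            start,
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": tol, "fatol": tol},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    state.free[nxt] = best_x
    return _cost_subset(state, inserted, target, squared)


def _optimize_alpha(
    state: _State,
    inserted: list[int],
    d_orig: np.ndarray,
    squared: bool,
    max_iter: int,
    tol: float,
) -> float:
    target = _sub_target(d_orig, inserted)

    def fun(v: np.ndarray) -> float:
        state.alpha = float(v[0])
        return _cost_subset(state, inserted, target, squared)

    a0 = np.array([state.alpha])
    res = minimize(
        fun,
        a0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": tol, "fatol": tol},
    )
    if res.fun <= fun(a0):
        state.alpha = float(res.x[0])
    return _cost_subset(state, inserted, target, squared)


def _optimize_previous(
    state: _State,
    inserted: list[int],
    nxt: int,
    target: np.ndarray,
    squared: bool,
    joint: bool,
    max_iter: int,
    tol: float,
) -> float:
    prev = [i for i in inserted if i != nxt]
    if state.d_free == 0 or not prev:
        return _cost_subset(state, inserted, target, squared)
    if joint:
        _lbfgs_free(state, inserted, prev, target, squared, max_iter, tol)
    else:
        for p in prev:
            _optimize_new_point(state, inserted, p, target, squared, max_iter, tol)
    return _cost_subset(state, inserted, target, squared)


def _lbfgs_free(
    state: _State,
    idx: list[int],
    movable: list[int],
    target: np.ndarray,
    squared: bool,
    max_iter: int,
    tol: float,
) -> None:
    """Gradient descent on the free coordinates of ``movable`` points."""
    pos = {s: p for p, s in enumerate(idx)}
    rows = [pos[m] for m in movable]
    target_sq = squareform(target)

    def fun_grad(v: np.ndarray) -> tuple[float, np.ndarray]:
        state.free[movable] = v.reshape(len(movable), state.d_free)
        pts = state.points(idx)
        f = _pair_stress(pts, target, squared)
        g = _stress_gradient(pts, target_sq, squared)
        return f, g[rows, 1:].ravel()

    x0 = state.free[movable].ravel().copy()
    f0 = fun_grad(x0)[0]
    res = minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": tol},
    )
    if res.fun <= f0:
        state.free[movable] = res.x.reshape(len(movable), state.d_free)
    else:
        state.free[movable] = x0.reshape(len(movable), state.d_free)


def _repair_reflections(
    state: _State,
    idx: list[int],
    target: np.ndarray,
    target_full: np.ndarray,
    squared: bool,
    max_iter: int,
    tol: float,
) -> bool:
    """Try mirroring each point's free coordinates about their centroid.

    Stress surfaces have reflection basins: a point can settle on the
    wrong side of the free axis and gradient steps cannot carry it across.
    For each point, the mirrored placement is locally re-optimized and
    kept if the total stress drops.  Deterministic; returns True if any
    point moved.
    """
    improved = False
    for i in idx:
        before = _cost_subset(state, idx, target, squared)
        saved = state.free[i].copy()
        after = _optimize_new_point(
            state, idx, i, target, squared, max_iter, tol, target_full
        )
        if after < before - 1e-12:
            improved = True
        else:
            state.free[i] = saved
    return improved


def _polish(
    state: _State,
    idx: list[int],
    d_orig: np.ndarray,
    squared: bool,
    max_iter: int,
    tol: float,
) -> dict[str, Any]:
    """Joint refinement of alpha and every free coordinate."""
    target = _sub_target(d_orig, idx)
    target_sq = squareform(target)
    n, d_free = len(idx), state.d_free
    c = state.cov[idx]

    def fun_grad(v: np.ndarray) -> tuple[float, np.ndarray]:
        state.alpha = float(v[0])
        if d_free:
            state.free[idx] = v[1:].reshape(n, d_free)
        pts = state.points(idx)
        f = _pair_stress(pts, target, squared)
        g = _stress_gradient(pts, target_sq, squared)
        g_alpha = float(g[:, 0] @ c)
        if d_free:
            return f, np.concatenate([[g_alpha], g[:, 1:].ravel()])
        return f, np.array([g_alpha])

    def lbfgs_pass() -> float:
        x0 = np.concatenate([[state.alpha], state.free[idx].ravel()])
        f0 = fun_grad(x0)[0]
        res = minimize(
            fun_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5 * max_iter, "ftol": 1e-14, "gtol": 1e-12},
        )
        best = res.x if res.fun <= f0 else x0
        state.alpha = float(best[0])
        if d_free:
            state.free[idx] = best[1:].reshape(n, d_free)
        return _pair_stress(state.points(idx), target, squared)

    before = _pair_stress(state.points(idx), target, squared)
    after = lbfgs_pass()
    for _ in range(3):  # escape reflection basins, then re-polish
        if not d_free:
            break
        if not _repair_reflections(
            state, idx, target, d_orig, squared, max_iter, tol
        ):
            break
        after = lbfgs_pass()
    return {"stage": "polish", "costs": (before, after)}
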