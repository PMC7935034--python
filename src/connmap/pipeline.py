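"""End-to-end study workflows.

Two workflows mirror how the methods are used on a real cohort:

- :func:`run_descriptor_study` — collapse each subject to the four scalar
  descriptors (kappa, MEAN, LDA, FS) for each nodal metric, test the
  control/patient mean difference by permutation, and correlate each
  descriptor with kappa.
- :func:`run_manifold_study` — embed the cohort with ISOMAP and with CCML
  (constrained on a chosen descriptor), regress descriptors on the reduced
  space with leave-one-out errors, fit the logistic probability map and
  leave-one-out SVM accuracies in both spaces, fit the MARS generative
  model on the CCML space, and optionally traverse the covariate axis for
  one subject.

Both are deterministic given their seeds and return JSON-serializable
reports next to the fitted objects.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ccml import CcmlEmbedding, ccml_embed
from .features import (
    FeatureScores,
    correlate_scores,
    fs_scores,
    kappa_scores,
    lda_scores,
    mean_scores,
    permutation_test,
    reference_profile,
)
from .generative import fit_generative, traverse_covariate
from .isomap import (
    class_probability_map,
    isomap_embed,
    loo_covariate_error,
    svm_accuracy,
)
from .metrics import MetricMatrix

__all__ = ["RunConfig", "run_descriptor_study", "run_manifold_study"]


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs shared by the study workflows."""

    metric: str = "global_efficiency"
    density: float = 0.025
    k_neighbors: int = 4
    n_dims: int = 2
    covariate: str = "kappa"
    n_permutations: int = 10_000
    seed: int = 0
    fit_intercept: bool = True
    lda_shrinkage: float = 0.1
    traverse_subject: str | None = None
    traverse_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if self.covariate not in {"kappa", "mean", "lda", "fs"}:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _descriptors(
    controls: MetricMatrix,
    patients: MetricMatrix,
    config: RunConfig,
) -> dict[str, FeatureScores]:
    """All four scalar descriptors over the stacked cohort."""
    stacked = MetricMatrix(
        np.vstack([controls.values, patients.values]),
        controls.subject_ids + patients.subject_ids,
        controls.node_ids,
        controls.metric_name,
    )
    labels = np.concatenate(
        [np.zeros(controls.n_subjects, dtype=int),
         np.ones(patients.n_subjects, dtype=int)]
    )
    ref = reference_profile(controls)
    out = {
        "kappa": kappa_scores(stacked, ref, fit_intercept=config.fit_intercept),
        "mean": mean_scores(stacked),
    }
    try:
        out["lda"] = lda_scores(stacked, labels, shrinkage=config.lda_shrinkage)
    except ValueError:
        pass
    try:
        out["fs"] = fs_scores(stacked, labels)
    except ValueError:
        pass
    return out


def run_descriptor_study(
    cohorts: Mapping[str, tuple[MetricMatrix, MetricMatrix]],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Per (metric, descriptor): group mean difference, permutation p,
    and Pearson correlation with the kappa descriptor.

    ``cohorts`` maps a metric name to its (controls, patients) tables.
    Degenerate descriptors (for example MEAN of degree when every graph
    has the same edge count) yield NaN correlations rather than failing.
    """
    rows = []
    for metric_name, (controls, patients) in cohorts.items():
        scores = _descriptors(controls, patients, config)
        n_c = controls.n_subjects
        for method, fs in scores.items():
            ctrl, pat = fs.scores[:n_c], fs.scores[n_c:]
            diff = float(pat.mean() - ctrl.mean())
            if np.ptp(fs.scores) == 0:
                p = 1.0
            else:
                p = permutation_test(
                    pat, ctrl, config.n_permutations, seed=config.seed
                ).p_value
            if method == "kappa":
                corr = np.nan
            else:
                try:
                    corr = correlate_scores(scores["kappa"], fs)
                except ValueError:
                    corr = np.nan
            rows.append(
                {
                    "metric": metric_name,
                    "method": method,
                    "mean_diff": diff,
                    "p_value": p,
                    "corr_with_kappa": corr,
                }
            )
    return pd.DataFrame(rows)


def run_manifold_study(
    controls: MetricMatrix,
    patients: MetricMatrix,
    config: RunConfig = RunConfig(),
) -> dict[str, Any]:
    """ISOMAP + CCML comparison on one metric table.

    Returns a report dictionary with the embeddings, leave-one-out
    regression errors of every descriptor on the ISOMAP space, the
    logistic-map correlations, leave-one-out SVM accuracies in both
    reduced spaces, the generative fit summary, and the optional
    covariate-axis traversal.
    """
    stacked = MetricMatrix(
        np.vstack([controls.values, patients.values]),
        controls.subject_ids + patients.subject_ids,
        controls.node_ids,
        controls.metric_name,
    )
    labels = np.concatenate(
        [np.zeros(controls.n_subjects, dtype=int),
         np.ones(patients.n_subjects, dtype=int)]
    )
    scores = _descriptors(controls, patients, config)
    covariate = scores[config.covariate].scores

    emb = isomap_embed(stacked, k=config.k_neighbors, d=config.n_dims)
    cc = ccml_embed(
        stacked,
        covariate,
        d=config.n_dims,
        k=config.k_neighbors,
        seed=config.seed,
    )

    loo_rows = []
    for method, fs in scores.items():
        if np.ptp(fs.scores) == 0:
            continue
        rmse, max_err = loo_covariate_error(emb, fs.scores)
        loo_rows.append({"covariate": method, "rmse": rmse, "max_error": max_err})

    prob_map = class_probability_map(emb, labels)
    prob_corr = {}
    for method in ("kappa", "mean"):
        fs = scores.get(method)
        if fs is not None and np.ptp(fs.scores) > 0:
            r, _ = stats.pearsonr(prob_map.probabilities, fs.scores)
            prob_corr[method] = float(r)

    acc_isomap = svm_accuracy(emb.coords, labels)
    acc_ccml = svm_accuracy(cc.coords, labels)

    gen = fit_generative(cc, stacked)
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "n_controls": controls.n_subjects,
        "n_patients": patients.n_subjects,
        "isomap": {
            "coords": emb.coords,
            "residual_variance": emb.residual_variance,
            "svm_loo_accuracy": acc_isomap,
        },
        "ccml": {
            "coords": cc.coords,
            "alpha": cc.alpha,
            "cost": cc.cost,
            "insertion_order": list(cc.insertion_order),
            "cost_trace": [
                {k: v for k, v in t.items()} for t in cc.cost_trace
            ],
            "svm_loo_accuracy": acc_ccml,
        },
        "descriptor_scores": {m: fs.scores for m, fs in scores.items()},
        "loo_regression": loo_rows,
        "probability_map_correlations": prob_corr,
        "generative": {
            "per_node_rmse": gen.per_node_rmse(),
            "mean_rmse": float(gen.per_node_rmse().mean()),
        },
        "subject_ids": list(stacked.subject_ids),
        "labels": labels,
    }
    if config.traverse_subject is not None:
        profiles = traverse_covariate(
            gen, cc, config.traverse_subject, list(config.traverse_values)
        )
        report["traversal"] = {
            "subject": config.traverse_subject,
            "covariate_values": list(config.traverse_values),
            "profiles": np.vstack(profiles) if profiles else np.empty((0, 0)),
        }
    report["_objects"] = {
        "isomap": emb,
        "ccml": cc,
        "generative": gen,
        "scores": scores,
    }
    return report
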