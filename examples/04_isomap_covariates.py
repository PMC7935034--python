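"""ISOMAP embedding of a cohort and covariate regression on it.

Subjects become points in a 2-D reduced space whose geometry follows the
geodesic structure of their metric vectors; scalar descriptors are then
interpolated over that space and scored by leave-one-out error, and class
membership is modeled by logistic regression and an RBF SVM.
"""

import numpy as np
from scipy import stats

from connmap import (
    class_probability_map,
    isomap_embed,
    kappa_scores,
    loo_covariate_error,
    mean_scores,
    reference_profile,
    simulate_metric_cohort,
    svm_accuracy,
)

cohort = simulate_metric_cohort(90, 20, 17, -1.0, 0.15, seed=3)
stacked = cohort.stacked()
labels = cohort.labels
ref = reference_profile(cohort.controls)
kappa = kappa_scores(stacked, ref).scores
mean = mean_scores(stacked).scores

emb = isomap_embed(stacked, k=4, d=2)
print(f"ISOMAP residual variance: {emb.residual_variance:.4f}")

for name, cov in (("kappa", kappa), ("MEAN", mean)):
    rmse, max_err = loo_covariate_error(emb, cov)
    print(f"LOO regression of {name:<5} on the reduced space: "
          f"RMSE = {rmse:.3f}, M = {max_err:.3f}")
# Low errors mean the covariate varies smoothly across the reduced space
# and is predictable from it.

pm = class_probability_map(emb, labels)
r = stats.pearsonr(pm.probabilities, kappa)[0]
print(f"corr(logistic patient-probability, kappa) = {r:+.3f}")

print(f"LOO SVM accuracy in the ISOMAP space: {svm_accuracy(emb.coords, labels):.2f}")
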