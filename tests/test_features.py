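"""Scalar descriptors: kappa, MEAN, LDA, FS, permutation test, correlations."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from connmap import (
    FeatureScores,
    MetricMatrix,
    correlate_scores,
    fs_scores,
    hub_disruption_index,
    lda_scores,
    mean_score,
    permutation_test,
    reference_profile,
    simulate_metric_cohort,
)
from connmap.features import ReferenceProfile


def _table(values, metric="m") -> MetricMatrix:
    values = np.asarray(values, dtype=float)
    return MetricMatrix(
        values,
        tuple(f"S{i}" for i in range(values.shape[0])),
        tuple(f"n{j}" for j in range(values.shape[1])),
        metric,
    )


class TestReferenceProfile:
    def test_node_wise_mean(self):
        ref = reference_profile(_table([[1, 2], [3, 4]]))
        assert ref.h_bar.tolist() == [2, 3]
        assert ref.group_size == 2

    def test_single_control(self):
        ref = reference_profile(_table([[5, 6, 7]]))
        assert ref.h_bar.tolist() == [5, 6, 7]

    def test_constant_profile_has_zero_variance(self):
        ref = reference_profile(_table([[2, 2, 2], [2, 2, 2]]))
        assert ref.variance == 0.0


class TestHubDisruptionIndex:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.h = np.sort(rng.lognormal(size=40))
        self.ref = ReferenceProfile(self.h, 10)

    def test_identical_profile_gives_zero(self):
        fit = hub_disruption_index(self.h, self.ref)
        assert fit.kappa == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_doubled_profile_gives_one(self):
        fit = hub_disruption_index(2 * self.h, self.ref)
        assert fit.kappa == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_flat_profile_at_reference_mean_gives_minus_one(self):
        # closed form: slope of (c - h) on h is -1 when c is constant
        flat = np.full_like(self.h, self.h.mean())
        fit = hub_disruption_index(flat, self.ref)
        assert fit.kappa == pytest.approx(-1.0)

    def test_without_intercept_on_origin_line(self):
        fit = hub_disruption_index(1.5 * self.h, self.ref, fit_intercept=False)
        assert fit.kappa == pytest.approx(0.5)
        assert fit.intercept == 0.0

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(1)
        noisy = self.h + rng.normal(0, 0.3, self.h.size)
        fit = hub_disruption_index(noisy, self.ref)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_common_permutation_invariance(self):
        rng = np.random.default_rng(2)
        subject = self.h * 1.3 + rng.normal(0, 0.1, self.h.size)
        perm = rng.permutation(self.h.size)
        fit = hub_disruption_index(subject, self.ref)
        fit_p = hub_disruption_index(
            subject[perm], ReferenceProfile(self.h[perm], 10)
        )
        assert fit_p.kappa == pytest.approx(fit.kappa)

    def test_errors(self):
        with pytest.raises(ValueError, match="constant reference"):
            hub_disruption_index(self.h, ReferenceProfile(np.ones(40), 10))
        with pytest.raises(ValueError, match="length mismatch"):
            hub_disruption_index(self.h[:-1], self.ref)


class TestMeanScore:
    def test_basic(self):
        assert mean_score([1, 2, 3]) == 2.0
        assert mean_score(np.full(7, 4.2)) == pytest.approx(4.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        assert mean_score(v) == pytest.approx(mean_score(rng.permutation(v)))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_score([])


class TestLdaScores:
    def test_single_informative_feature(self):
        """Only feature 0 separates the classes: the discriminant aligns
        with axis 0 and scores are an affine transform of feature 0."""
        rng = np.random.default_rng(0)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        x0 = rng.normal(0, 1, n) + 5.0 * labels
        x1 = rng.normal(0, 1, n)
        table = _table(np.column_stack([x0, x1]))
        fs = lda_scores(table, labels, shrinkage=0.0)
        w = fs.detail["weights"]
        assert abs(w[0]) / (abs(w[1]) + 1e-30) > 10
        r = np.corrcoef(fs.scores, x0)[0, 1]
        assert abs(r) > 0.98

    def test_label_swap_negates_scores(self):
        rng = np.random.default_rng(1)
        table = _table(rng.normal(size=(12, 5)))
        labels = np.repeat([0, 1], 6)
        a = lda_scores(table, labels)
        b = lda_scores(table, 1 - labels)
        assert a.scores == pytest.approx(-b.scores)

    def test_identical_means_raise(self):
        x = np.vstack([np.eye(3), np.eye(3)])
        with pytest.raises(ValueError, match="identical class means"):
            lda_scores(_table(x), np.repeat([0, 1], 3))

    def test_hdlss_regularization_keeps_direction_finite(self):
        rng = np.random.default_rng(2)
        table = _table(rng.normal(size=(10, 50)))  # nodes >> subjects
        labels = np.repeat([0, 1], 5)
        fs = lda_scores(table, labels)
        assert np.isfinite(fs.scores).all()

    def test_fisher_beats_single_feature_separation(self):
        """The LDA group-mean gap (scaled by within-class sd) is at least
        that of every single node column."""
        rng = np.random.default_rng(3)
        n = 30
        labels = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 4))
        x[:, 1] += 1.5 * labels
        x[:, 3] += 0.8 * labels
        table = _table(x)

        def separation(v):
            a, b = v[labels == 0], v[labels == 1]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        lda_sep = separation(lda_scores(table, labels, shrinkage=0.0).scores)
        for j in range(4):
            assert lda_sep >= separation(x[:, j]) - 1e-9


class TestFsScores:
    def test_selects_shifted_node(self):
        rng = np.random.default_rng(0)
        n = 30
        labels = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 6))
        x[:, 3] += 10.0 * labels
        fs = fs_scores(_table(x), labels)
        assert fs.detail["node_index"] == 3
        assert fs.scores == pytest.approx(x[:, 3])
        # oracle: brute-force t statistics column by column
        for j in range(6):
            t, _ = stats.ttest_ind(x[labels == 1, j], x[labels == 0, j])
            assert fs.detail["t_statistics"][j] == pytest.approx(t)

    def test_label_swap_selects_same_node(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 5))
        labels = np.repeat([0, 1], 10)
        a = fs_scores(_table(x), labels)
        b = fs_scores(_table(x), 1 - labels)
        assert a.detail["node_index"] == b.detail["node_index"]

    def test_zero_variance_column_gets_zero_t(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3))
        x[:, 0] = 7.0
        fs = fs_scores(_table(x), np.repeat([0, 1], 5))
        assert fs.detail["t_statistics"][0] == 0.0

    def test_tie_breaks_to_lowest_index(self):
        x = np.tile([[0.0], [1.0]], (5, 3))  # identical columns
        fs = fs_scores(_table(x), np.repeat([0, 1], 5)[np.argsort(np.tile([0, 1], 5))])
        assert fs.detail["node_index"] == 0


class TestPermutationTest:
    def test_far_separated_groups_hit_lower_bound(self):
        """With no shuffled split as extreme as the observed one, the
        add-one estimator bounds p at 1/(B+1)."""
        a = np.arange(15) + 1000.0
        b = np.arange(15.0)
        res = permutation_test(a, b, 10_000, seed=0)
        assert res.p_value == pytest.approx(1 / 10_001)
        assert not res.exhaustive

    def test_identical_constant_groups_give_p_one(self):
        res = permutation_test(np.ones(5), np.ones(5), 500, seed=0)
        assert res.p_value == 1.0

    def test_single_permutation_p_in_half_or_one(self):
        rng = np.random.default_rng(0)
        ps = set()
        for seed in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8)
            ps.add(permutation_test(a, b, 1, seed=seed).p_value)
        assert ps <= {0.5, 1.0}

    def test_exhaustive_enumeration_on_tiny_groups(self):
        a, b = np.array([10.0, 11.0]), np.array([0.0, 1.0])
        res = permutation_test(a, b, 10_000, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 6  # C(4, 2)
        # only the observed split and its mirror reach |diff| = 10
        assert res.p_value == pytest.approx(2 / 6)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=9), rng.normal(size=9)
        r1 = permutation_test(a, b, 300, seed=42)
        r2 = permutation_test(a, b, 300, seed=42)
        assert r1.p_value == r2.p_value

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            permutation_test(np.array([]), np.ones(3), 10)


class TestCorrelateScores:
    def _scores(self, v, method="m"):
        return FeatureScores(method, v, tuple(f"S{i}" for i in range(len(v))))

    def test_self_and_negated(self):
        v = np.arange(10.0)
        assert correlate_scores(self._scores(v), self._scores(v)) == pytest.approx(1.0)
        assert correlate_scores(self._scores(v), self._scores(-v)) == pytest.approx(-1.0)

    def test_gram_schmidt_orthogonal_pair(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        a = a - a.mean()
        b = b - b.mean()
        b -= (a @ b) / (a @ a) * a  # orthogonalize against centered a
        r = correlate_scores(self._scores(a), self._scores(b))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_scores(self._scores(np.ones(5)), self._scores(np.arange(5.0)))


class TestKappaRecovery:
    def test_noiseless_grid_recovered_to_machine_precision(self):
        grid = [-1.5, -1.0, 0.0, 1.0, 1.5]
        cohort = simulate_metric_cohort(90, 10, len(grid), grid, 0.0, seed=0)
        ref = reference_profile(cohort.controls)
        for row, k_true in zip(cohort.patients.values, cohort.true_kappa):
            fit = hub_disruption_index(row, ref)
            assert fit.kappa == pytest.approx(k_true, abs=1e-10)

    def test_null_permutation_calibration(self):
        """Rejection rate at alpha = 0.05 stays near nominal under the null."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            a, b = rng.normal(size=(2, 10))
            res = permutation_test(a, b, 200, seed=rep)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08
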