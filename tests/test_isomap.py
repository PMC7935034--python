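"""ISOMAP embedding, covariate surfaces, logistic map, and SVM scoring."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from connmap import (
    class_probability_map,
    fit_covariate_surface,
    geodesic_distances,
    isomap_embed,
    loo_covariate_error,
    svm_accuracy,
)


class TestIsomapEmbed:
    def test_collinear_points_keep_gaps(self):
        """An isometric line embeds with consecutive gaps preserved."""
        t = np.sort(np.random.default_rng(0).uniform(0, 10, 10))
        direction = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        x = t[:, None] * direction
        emb = isomap_embed(x, k=4, d=1)
        # isometry up to reflection: all pairwise gaps preserved
        assert pdist(emb.coords) == pytest.approx(pdist(t[:, None]), abs=1e-9)

    def test_quarter_circle_unrolls_to_arc_length(self):
        """1-D reduction of a quarter-circle arc approximates arc length."""
        n = 200
        theta = np.linspace(0, np.pi / 2, n)
        x = np.column_stack([np.cos(theta), np.sin(theta)])
        emb = isomap_embed(x, k=4, d=1)
        coord = np.sort(emb.coords[:, 0])
        arc = theta - theta.mean()  # analytic arc-length oracle (radius 1)
        d_emb = pdist(coord[:, None])
        d_arc = pdist(arc[:, None])
        rel = np.abs(d_emb - d_arc) / d_arc
        assert rel.max() < 0.02

    def test_full_graph_equals_pca(self):
        """With a complete neighbor graph ISOMAP reduces to classical
        MDS = PCA: pairwise reduced distances match PCA score distances."""
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(30, 2)) * [3.0, 1.0]
        basis, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        x = scores @ basis.T
        emb = isomap_embed(x, k=29, d=2)
        xc = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        d_pca = pdist(u[:, :2] * s[:2])
        assert np.max(np.abs(pdist(emb.coords) - d_pca)) < 1e-6

    def test_matches_sklearn_isomap_distances(self):
        """Independent oracle: sklearn's Isomap on a connected cloud."""
        from sklearn.manifold import Isomap

        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 5))
        emb = isomap_embed(x, k=6, d=2)
        sk = Isomap(n_neighbors=6, n_components=2).fit_transform(x)
        assert pdist(emb.coords) == pytest.approx(pdist(sk), abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = x @ q + np.array([5.0, -2.0, 1.0])
        a = isomap_embed(x, k=5, d=2).coords
        b = isomap_embed(moved, k=5, d=2).coords
        _, _, disparity = procrustes(a, b)
        assert disparity < 1e-6

    def test_residual_variance_nonincreasing_in_d(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 6))
        resid = [isomap_embed(x, k=5, d=d).residual_variance for d in (1, 2, 3, 4)]
        assert all(a >= b - 1e-12 for a, b in zip(resid, resid[1:]))

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            isomap_embed(np.zeros((2, 3)), d=2)

    def test_disconnected_without_bridging_raises(self):
        x = np.vstack([np.zeros((5, 2)) + [0, 0], np.zeros((5, 2)) + [100, 0]])
        x += np.random.default_rng(5).normal(0, 0.01, x.shape)
        with pytest.raises(ValueError, match="components"):
            isomap_embed(x, k=2, d=1, bridge_components=False)
        emb = isomap_embed(x, k=2, d=1)  # bridging on: succeeds
        assert np.isfinite(emb.coords).all()


class TestGeodesicDistances:
    def test_geodesic_at_least_euclidean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        geo = geodesic_distances(x, k=4)
        eu = squareform(pdist(x))
        assert (geo >= eu - 1e-9).all()

    def test_symmetric_zero_diagonal_finite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        geo = geodesic_distances(x, k=2)
        assert np.allclose(geo, geo.T)
        assert np.diag(geo) == pytest.approx(np.zeros(20))
        assert np.isfinite(geo).all()


class TestCovariateSurface:
    def test_affine_covariate_reproduced(self):
        """Thin-plate splines reproduce affine functions exactly."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(-1, 1, (30, 2))
        cov = 2.0 * coords[:, 0] - 0.5 * coords[:, 1] + 3.0
        surf = fit_covariate_surface(coords, cov)
        query = rng.uniform(-0.8, 0.8, (50, 2))
        expected = 2.0 * query[:, 0] - 0.5 * query[:, 1] + 3.0
        assert surf(query) == pytest.approx(expected, abs=1e-6)

    def test_constant_covariate(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(15, 2))
        surf = fit_covariate_surface(coords, np.full(15, 4.0))
        assert surf(rng.normal(size=(10, 2))) == pytest.approx(np.full(10, 4.0))

    def test_interpolates_training_points(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(20, 2))
        cov = rng.normal(size=20)
        surf = fit_covariate_surface(coords, cov)
        assert surf(coords) == pytest.approx(cov, abs=1e-8)

    def test_gaussian_kernel_also_interpolates(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(15, 2))
        cov = rng.normal(size=15)
        surf = fit_covariate_surface(coords, cov, kernel="gaussian")
        assert surf(coords) == pytest.approx(cov, abs=1e-6)


class TestLooCovariateError:
    def test_constant_covariate_zero_errors(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(12, 2))
        rmse, max_err = loo_covariate_error(coords, np.full(12, 2.5))
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert max_err == pytest.approx(0.0, abs=1e-9)

    def test_max_at_least_rmse(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(15, 2))
        rmse, max_err = loo_covariate_error(coords, rng.normal(size=15))
        assert max_err >= rmse

    def test_affine_covariate_dense_cloud_near_zero(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-1, 1, (60, 2))
        cov = coords[:, 0] - 0.3 * coords[:, 1]
        rmse, _ = loo_covariate_error(coords, cov)
        assert rmse < 1e-6  # affine reproduction holds leave-one-out


class TestClassProbabilityMap:
    def test_separated_clusters(self):
        rng = np.random.default_rng(0)
        coords = np.vstack(
            [rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))]
        )
        labels = np.repeat([0, 1], 10)
        pm = class_probability_map(coords, labels)
        assert (pm.probabilities[:10] < 0.5).all()
        assert (pm.probabilities[10:] > 0.5).all()
        assert ((pm.probabilities > 0) & (pm.probabilities < 1)).all()

    def test_label_swap_flips_probabilities(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 2))
        labels = np.repeat([0, 1], 10)
        p = class_probability_map(coords, labels).probabilities
        q = class_probability_map(coords, 1 - labels).probabilities
        assert p == pytest.approx(1 - q, abs=1e-8)

    def test_uninformative_coords_near_half(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(200, 2))
        labels = np.tile([0, 1], 100)  # independent of coords, balanced
        pm = class_probability_map(coords, labels)
        assert np.abs(pm.probabilities - 0.5).mean() < 0.1

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            class_probability_map(np.zeros((5, 2)), np.zeros(5))


class TestSvmAccuracy:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(0)
        coords = np.vstack(
            [rng.normal(0, 1.0, (10, 2)), rng.normal(10, 1.0, (10, 2))]
        )
        labels = np.repeat([0, 1], 10)
        assert svm_accuracy(coords, labels) == 1.0

    def test_identical_coords_chance_level(self):
        coords = np.zeros((20, 2))
        labels = np.repeat([0, 1], [14, 6])
        acc = svm_accuracy(coords, labels)
        assert acc == pytest.approx(14 / 20, abs=0.1)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(16, 2))
        coords[8:] += 3.0
        labels = np.repeat([0, 1], 8)
        perm = rng.permutation(16)
        assert svm_accuracy(coords, labels) == svm_accuracy(
            coords[perm], labels[perm]
        )

    def test_degenerate_class_sizes_raise(self):
        with pytest.raises(ValueError):
            svm_accuracy(np.zeros((5, 2)), np.array([0, 0, 0, 0, 1]))
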