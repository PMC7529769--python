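import numpy as np
import pytest
from sklearn.cluster import KMeans

from seasonomics.clustering import (ClusteringError, ClusterModel, CurveMatrix,
                                    EmptySelection, fuzzy_cmeans, hard_labels,
                                    pca_summary, project_membership, select_k,
                                    standardize_curve, standardize_curves)
from seasonomics.cohort import archetype_curve
from seasonomics.seasonal import SeasonalFit

DAYS = np.arange(1, 366, dtype=float)


def _fit_stub(fid, curve, pvalue):
    return SeasonalFit(feature_id=fid, n_obs=100, beta=np.empty(0),
                       cov=np.empty((0, 0)), lambda_=1.0, lambda_subject=1.0,
                       edf_smooth=5.0, edf_total=10.0, rss=1.0, sigma2=1.0,
                       fitted_curve=np.asarray(curve, float),
                       curve_sd=np.zeros(365), pvalue=pvalue)


def _archetype_family(pattern, n, noise, rng, jitter=10.0):
    return np.vstack([
        standardize_curve(np.asarray(archetype_curve(pattern, DAYS - rng.uniform(-jitter, jitter)))
                          + rng.normal(0, noise, 365))
        for _ in range(n)])


class TestStandardize:
    def test_rows_standardized_and_filtered(self):
        rng = np.random.default_rng(0)
        fits = [
            _fit_stub("keep1", np.sin(2 * np.pi * DAYS / 365), 0.01),
            _fit_stub("keep2", rng.normal(0, 1, 365), 0.04),
            _fit_stub("dropped_p", np.cos(2 * np.pi * DAYS / 365), 0.5),
            _fit_stub("dropped_const", np.full(365, 2.0), 0.001),
        ]
        cm = standardize_curves(fits, p_threshold=0.05)
        assert cm.feature_ids == ["keep1", "keep2"]
        assert cm.excluded == ["dropped_const"]
        np.testing.assert_allclose(cm.matrix.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(cm.matrix.std(axis=1), 1.0, atol=1e-8)

    def test_nothing_passes_raises(self):
        with pytest.raises(EmptySelection):
            standardize_curves([_fit_stub("a", np.sin(DAYS), 0.9)], 0.05)


class TestFuzzyCMeans:
    def test_k1_centroid_is_columnwise_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 365))
        model = fuzzy_cmeans(X, k=1)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(model.membership, 1.0)

    def test_two_families_recovered_against_family_mean_oracle(self):
        rng = np.random.default_rng(2)
        A = _archetype_family(1, 25, 0.1, rng)
        B = _archetype_family(2, 25, 0.1, rng)
        model = fuzzy_cmeans(np.vstack([A, B]), k=2, m=2.0, seed=3)
        oracles = [A.mean(axis=0), B.mean(axis=0)]
        # match centroids to family means by distance
        d = np.array([[np.linalg.norm(c - o) for o in oracles]
                      for c in model.centroids])
        order = d.argmin(axis=1)
        assert sorted(order) == [0, 1]
        for c, j in zip(model.centroids, order):
            assert np.linalg.norm(c - oracles[j]) < 0.15 * np.linalg.norm(oracles[j])
        uA = project_membership(standardize_curve(oracles[0]), model)
        assert uA[np.where(order == 0)[0][0]] > 0.95

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 365))
        model = fuzzy_cmeans(X, k=4, seed=0)
        np.testing.assert_allclose(model.membership.sum(axis=1), 1.0, atol=1e-8)

    def test_objective_nonincreasing_with_iterations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 50))
        objs = [fuzzy_cmeans(X, k=3, seed=7, n_restarts=1, max_iter=it).objective
                for it in (1, 2, 4, 8, 16, 64)]
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_near_hard_limit_agrees_with_kmeans(self):
        rng = np.random.default_rng(6)
        A = _archetype_family(1, 30, 0.1, rng)
        B = _archetype_family(2, 30, 0.1, rng)
        X = np.vstack([A, B])
        model = fuzzy_cmeans(X, k=2, m=1.05, seed=1)
        ours = hard_labels(model)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(X)
        agree = max(np.mean(ours == km), np.mean(ours != km))
        assert agree >= 0.95

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ClusteringError):
            fuzzy_cmeans(np.zeros((3, 10)), k=4)

    def test_bad_fuzzifier_rejected(self):
        with pytest.raises(ClusteringError):
            fuzzy_cmeans(np.zeros((5, 10)), k=2, m=1.0)


class TestProjection:
    def test_centroid_projects_to_unit_vector(self):
        rng = np.random.default_rng(7)
        model = fuzzy_cmeans(rng.normal(0, 1, (20, 365)), k=3, seed=2)
        for j in range(3):
            u = project_membership(model.centroids[j], model)
            np.testing.assert_allclose(u, np.eye(3)[j], atol=1e-12)

    def test_hand_evaluated_memberships_distances_1_and_3(self):
        model = ClusterModel(k=2, m=2.0,
                             centroids=np.array([[0.0, 0.0], [4.0, 0.0]]),
                             membership=np.empty((0, 2)), objective=0.0,
                             seed=None, n_restarts=0)
        u = project_membership(np.array([1.0, 0.0]), model)
        np.testing.assert_allclose(u, [0.9, 0.1], atol=1e-12)

    def test_equidistant_point_splits_evenly(self):
        model = ClusterModel(k=2, m=2.0,
                             centroids=np.array([[-1.0, 0.0], [1.0, 0.0]]),
                             membership=np.empty((0, 2)), objective=0.0,
                             seed=None, n_restarts=0)
        u = project_membership(np.array([0.0, 5.0]), model)
        np.testing.assert_allclose(u, [0.5, 0.5], atol=1e-12)


class TestSelectK:
    def test_two_archetypes_choose_k2(self):
        rng = np.random.default_rng(8)
        X = np.vstack([_archetype_family(1, 50, 0.3, rng),
                       _archetype_family(2, 50, 0.3, rng)])
        assert select_k(X, range(2, 11), seed=0).chosen_k == 2

    def test_three_separated_families_choose_k3(self):
        rng = np.random.default_rng(9)
        fam3 = np.vstack([
            standardize_curve(np.sin(6 * np.pi * DAYS / 365) + rng.normal(0, 0.2, 365))
            for _ in range(30)])
        X = np.vstack([_archetype_family(1, 30, 0.2, rng, jitter=5),
                       _archetype_family(2, 30, 0.2, rng, jitter=5), fam3])
        assert select_k(X, range(2, 8), seed=0).chosen_k == 3

    def test_structureless_noise_low_silhouette(self):
        rng = np.random.default_rng(10)
        X = np.vstack([standardize_curve(rng.normal(0, 1, 365)) for _ in range(60)])
        report = select_k(X, range(2, 8), seed=0)
        assert max(report.silhouette) < 0.3

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (25, 100))
        a = select_k(X, range(2, 6), seed=5)
        b = select_k(X, range(2, 6), seed=5)
        assert a.chosen_k == b.chosen_k
        np.testing.assert_array_equal(a.silhouette, b.silhouette)

    def test_empty_k_range_rejected(self):
        with pytest.raises(ClusteringError):
            select_k(np.zeros((3, 10)), range(2, 2))


class TestPCA:
    def test_planar_curves_fully_explained_by_two_pcs(self):
        rng = np.random.default_rng(12)
        basis = rng.normal(0, 1, (2, 365))
        X = rng.normal(0, 1, (30, 2)) @ basis
        _, frac = pca_summary(X)
        assert frac[:2].sum() == pytest.approx(1.0, abs=1e-10)

    def test_variance_fractions_sum_to_one_nonincreasing(self):
        rng = np.random.default_rng(13)
        _, frac = pca_summary(rng.normal(0, 1, (20, 30)))
        assert frac.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(frac) <= 1e-12).all()

    def test_two_archetype_families_mostly_planar(self):
        rng = np.random.default_rng(14)
        X = np.vstack([_archetype_family(1, 40, 0.3, rng),
                       _archetype_family(2, 40, 0.3, rng)])
        _, frac = pca_summary(X)
        assert frac[:2].sum() > 0.8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ClusteringError):
            pca_summary(np.zeros((2, 10)))
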