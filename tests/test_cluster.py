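"""k-means wrapper, k-selection and canonical-archetype labeling tests."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import cogclust as cc
from cogclust.cluster import CanonicalLabelMap, _elbow_knee
from cogclust.exceptions import InputError


def two_blob_points(n=200, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([25.0, 0.0], [1.0, 0.8], size=(n // 2, 2))
    b = rng.normal([10.0, -8.0], [1.0, 0.8], size=(n // 2, 2))
    return np.vstack([a, b])


class TestFitKmeans:
    def test_repeated_locations_give_zero_inertia(self):
        locations = np.array([[25.0, 0.0], [20.0, -5.0], [10.0, -10.0]])
        points = np.repeat(locations, 30, axis=0)
        fit = cc.fit_kmeans(points, k=3, seed=1)
        assert fit.inertia == pytest.approx(0.0, abs=1e-9)
        assert {tuple(np.round(c, 6)) for c in fit.centroids} == {
            tuple(row) for row in locations
        }

    def test_single_cluster_centroid_is_sample_mean(self):
        rng = np.random.default_rng(4)
        points = rng.normal([20.0, -2.0], [3.0, 2.0], size=(500, 2))
        fit = cc.fit_kmeans(points, k=1, seed=0)
        assert np.allclose(fit.centroids[0], points.mean(axis=0), atol=1e-8)

    def test_identical_inputs_identical_results(self):
        points = two_blob_points()
        a = cc.fit_kmeans(points, k=2, seed=9)
        b = cc.fit_kmeans(points, k=2, seed=9)
        assert np.array_equal(a.assignment, b.assignment)
        assert np.allclose(a.centroids, b.centroids)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            cc.fit_kmeans(np.array([[1.0, 2.0], [3.0, 1.0]]), k=3, seed=0)

    def test_constant_column_rejected(self):
        points = np.column_stack([np.arange(10.0), np.zeros(10)])
        with pytest.raises(InputError):
            cc.fit_kmeans(points, k=2, seed=0)

    def test_inertia_nonincreasing_in_k(self):
        points = two_blob_points(n=300, seed=2)
        inertias = [cc.fit_kmeans(points, k=k, seed=0).inertia for k in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_recovers_true_components(self, big_cohort, followup1_fit):
        """On the default generator the 4-means fit matches the true components
        for >=95% of rows and reaches adjusted Rand >= 0.9."""
        fit, labels = followup1_fit
        t1 = big_cohort["tables"][1]
        truth = big_cohort["truth"].components
        tc = truth[truth["followup_index"] == 1].set_index("patient_id")["component"]
        true = tc.loc[t1["patient_id"]].to_numpy()
        assert (labels == true).mean() >= 0.95
        assert adjusted_rand_score(true, labels) >= 0.9


class TestKSelection:
    def test_two_blobs_silhouette_and_selection(self):
        diag = cc.k_diagnostics(two_blob_points(), k_range=range(1, 7), seed=3)
        sil_k = diag.k_range[np.nanargmax(diag.silhouette)]
        assert sil_k == 2
        assert cc.select_k(diag) == 2

    def test_uniform_square_gap_selects_one(self):
        rng = np.random.default_rng(8)
        points = rng.uniform([0, 0], [30, 30], size=(400, 2))
        diag = cc.k_diagnostics(points, k_range=range(1, 7), seed=8)
        chosen, candidates = cc.select_k(diag, return_candidates=True)
        assert candidates["gap"] == 1
        assert chosen == 1

    def test_inertia_at_k_equals_n_is_zero(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(12, 2)) * 5 + [20, -3]
        diag = cc.k_diagnostics(points, k_range=[1, 2, 12], seed=0, n_reference=3)
        assert diag.inertia[-1] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_points_rejected(self):
        with pytest.raises(InputError):
            cc.k_diagnostics(np.ones((50, 2)), k_range=range(1, 4), seed=0)

    def test_elbow_knee_finds_max_curvature(self):
        ks = np.arange(1, 9)
        inertia = np.array([100.0, 60.0, 35.0, 10.0, 9.0, 8.2, 7.6, 7.1])
        assert _elbow_knee(ks, inertia) == 4


class TestCanonicalize:
    def test_archetype_matching_on_reference_centroids(self):
        result = cc.ClusterResult(
            k=4,
            centroids=np.array(
                [[25.0, 0.0], [24.0, -6.0], [15.0, -1.0], [12.0, -10.0]]
            ),
            assignment=np.arange(4),
            inertia=0.0,
            seed=0,
        )
        mapping = cc.canonicalize(result).mapping
        assert mapping == {0: 1, 1: 2, 2: 3, 3: 4}

    def test_invariant_under_raw_index_permutation(self, followup1_fit):
        fit, labels = followup1_fit
        permutation = np.array([2, 0, 3, 1])
        permuted = cc.ClusterResult(
            k=4,
            centroids=fit.centroids[permutation],
            assignment=np.argsort(permutation)[fit.assignment],
            inertia=fit.inertia,
            seed=fit.seed,
        )
        relabeled = cc.canonicalize(permuted).apply(permuted.assignment)
        assert np.array_equal(relabeled, labels)

    def test_different_seeds_same_canonical_labels(self, big_cohort):
        points = big_cohort["tables"][1][["mmse_score", "mmse_decline"]].to_numpy()
        runs = []
        for seed in (1, 99):
            fit = cc.fit_kmeans(points, k=4, seed=seed)
            runs.append(cc.canonicalize(fit).apply(fit.assignment))
        assert np.array_equal(runs[0], runs[1])

    def test_label_one_centroid_dominates(self, followup1_fit):
        """The canonical label-1 centroid has the highest MMSE score and the
        least negative decline of the four."""
        fit, _ = followup1_fit
        mapping = cc.canonicalize(fit).mapping
        by_label = {label: fit.centroids[raw] for raw, label in mapping.items()}
        assert by_label[1][0] == max(c[0] for c in by_label.values())
        assert by_label[1][1] == max(c[1] for c in by_label.values())

    def test_unsupported_k_rejected(self):
        fit = cc.fit_kmeans(two_blob_points(), k=2, seed=0)
        with pytest.raises(InputError):
            cc.canonicalize(fit)

    def test_apply_maps_assignments(self):
        label_map = CanonicalLabelMap({0: 3, 1: 1, 2: 4, 3: 2})
        out = label_map.apply(np.array([0, 1, 2, 3, 1]))
        assert out.tolist() == [3, 1, 4, 2, 1]
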