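"""Tests for dimension reduction, k-means subtyping and signatures."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
import sklearn.metrics

from lracluster import (
    OmicsBlock,
    ParameterMatrix,
    ReducedRepresentation,
    SolverConfig,
    best_k,
    fit,
    kmeans_cluster,
    reduce,
    scan_clusters,
    signature_features,
    silhouette_value,
)
from lracluster.reduce_cluster import silhouette_samples


def silhouette_brute_force(coords, labels):
    """O(n^2) textbook silhouette, written independently of the package."""
    X = np.asarray(coords).T
    labels = np.asarray(labels)
    vals = []
    for i in range(len(X)):
        same = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def blob_representation(rng, centers, n_per, noise=1.0):
    pts = np.vstack(
        [c + noise * rng.standard_normal((n_per, len(c))) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return ReducedRepresentation(coords=pts.T), labels


class TestReduce:
    def test_rank_one_outer_product(self):
        u = np.array([[0.6], [0.8]])
        v = np.array([[1.0, 1.0]]) / np.sqrt(2)
        pm = ParameterMatrix(2.0 * u @ v, {"b": (0, 2)}, ["s1", "s2"])
        rep = reduce(pm, 1)
        assert np.allclose(rep.coords, [[np.sqrt(2), np.sqrt(2)]], atol=1e-12)
        assert rep.singular_values[0] == pytest.approx(2.0)

    def test_zero_theta_warns_and_returns_zeros(self):
        pm = ParameterMatrix(np.zeros((3, 4)), {"b": (0, 3)})
        with pytest.warns(UserWarning, match="non-zero singular"):
            rep = reduce(pm, 2)
        assert np.allclose(rep.coords, 0.0)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(0)
        pm = ParameterMatrix(rng.standard_normal((5, 6)), {"b": (0, 5)})
        r1, r2 = reduce(pm, 2), reduce(pm, 2)
        assert np.array_equal(r1.coords, r2.coords)
        for row in r1.coords:
            assert row[np.argmax(np.abs(row))] >= 0

    def test_gaussian_fit_coordinates_match_pca_scores(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 40))
        X += rng.standard_normal((50, 3)) @ (2.5 * rng.standard_normal((3, 40)))
        X -= X.mean(axis=1, keepdims=True)
        res = fit([OmicsBlock("g", X, "gaussian")], SolverConfig(rank=3, tol=1e-10, max_iter=300))
        rep = reduce(res.theta, 3)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        pca_scores = s[:3, None] * Vt[:3]
        for i in range(3):
            r = np.corrcoef(rep.coords[i], pca_scores[i])[0, 1]
            assert abs(r) > 0.999


class TestKMeans:
    def test_two_well_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        rep, truth = blob_representation(rng, [np.array([-5.0, 0]), np.array([5.0, 0])], 50)
        res = kmeans_cluster(rep, k=2, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert set(res.labels) == {1, 2}

    def test_identical_points_degenerate_silhouette_zero(self):
        rep = ReducedRepresentation(coords=np.ones((2, 8)))
        with pytest.warns(UserWarning, match="coincide"):
            res = kmeans_cluster(rep, k=2, seed=0)
        assert res.silhouette == 0.0

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(2)
        rep, _ = blob_representation(rng, [np.zeros(2), np.ones(2)], 30)
        a = kmeans_cluster(rep, k=3, seed=7)
        b = kmeans_cluster(rep, k=3, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_k_larger_than_samples_rejected(self):
        rep = ReducedRepresentation(coords=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(rep, k=4)


class TestSilhouette:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for n in (10, 25, 50):
            coords = rng.standard_normal((3, n))
            labels = rng.integers(0, 3, n)
            if len(set(labels)) < 2:
                labels[0] = (labels[0] + 1) % 3
            assert silhouette_value(coords, labels) == pytest.approx(
                silhouette_brute_force(coords, labels), abs=1e-10
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(4)
        coords = rng.standard_normal((2, 40))
        labels = rng.integers(0, 4, 40)
        ours = silhouette_samples(coords, labels)
        ref = sklearn.metrics.silhouette_samples(coords.T, labels)
        assert np.allclose(ours, ref, atol=1e-10)

    def test_separated_pairs_approach_one(self):
        coords = np.array([[-100.0, -100.5, 100.0, 100.5]])
        assert silhouette_value(coords, [0, 0, 1, 1]) > 0.99

    def test_random_labels_on_one_blob_near_zero(self):
        rng = np.random.default_rng(6)
        coords = rng.standard_normal((2, 200))
        labels = rng.integers(0, 2, 200)
        assert abs(silhouette_value(coords, labels)) < 0.1

    def test_singleton_clusters_score_zero(self):
        assert silhouette_value(np.array([[0.0, 1.0]]), [0, 1]) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette_value(np.zeros((2, 4)), [1, 1, 1, 1])


class TestClusterScan:
    def test_three_blobs_argmax_at_three(self):
        rng = np.random.default_rng(9)
        centers = [np.array([0.0, 0]), np.array([8.0, 0]), np.array([4.0, 7.0])]
        rep, _ = blob_representation(rng, centers, 30)
        curve = scan_clusters(rep, range(2, 7), seed=0)
        assert best_k(curve) == 3
        sils = {e.k: e.silhouette for e in curve}
        assert sils[3] > sils[2] and sils[3] > sils[4]

    def test_single_k_scan(self):
        rng = np.random.default_rng(10)
        rep, _ = blob_representation(rng, [np.zeros(2), 5 * np.ones(2)], 10)
        curve = scan_clusters(rep, [2], seed=0)
        assert len(curve) == 1 and curve[0].k == 2


class TestSignatures:
    @pytest.fixture()
    def shifted_dataset(self):
        rng = np.random.default_rng(12)
        labels = np.repeat([1, 2], 50)
        g = rng.standard_normal((20, 100))
        g[0, labels == 1] += 5.0  # planted shift in cluster 1
        binary = rng.integers(0, 2, (5, 100)).astype(float)
        binary[2] = (labels == 1).astype(float)  # present only in cluster 1
        g[7] = 1.0  # constant feature
        blocks = [
            OmicsBlock("expr", g, "gaussian"),
            OmicsBlock("mut", binary, "binary"),
        ]
        return blocks, labels

    def test_planted_shift_ranked_first_among_gaussian(self, shifted_dataset):
        blocks, labels = shifted_dataset
        table = signature_features(blocks, labels, 1)
        gaussian_rows = table[table.block == "expr"]
        assert gaussian_rows.iloc[0].feature_id == "expr_f0"
        assert gaussian_rows.iloc[0].adj_p < 1e-6
        assert gaussian_rows.iloc[0].direction == "up"

    def test_perfectly_separating_binary_feature_top_ranked(self, shifted_dataset):
        blocks, labels = shifted_dataset
        table = signature_features(blocks, labels, 1)
        binary_rows = table[table.block == "mut"]
        assert binary_rows.iloc[0].feature_id == "mut_f2"
        assert binary_rows.iloc[0].direction == "up"

    def test_null_feature_large_p(self, shifted_dataset):
        blocks, labels = shifted_dataset
        table = signature_features(blocks, labels, 1).set_index("feature_id")
        null_ps = table.loc[[f"expr_f{i}" for i in range(10, 20)], "adj_p"]
        assert (null_ps > 0.5).mean() > 0.7

    def test_constant_feature_flagged_p_one(self, shifted_dataset):
        blocks, labels = shifted_dataset
        table = signature_features(blocks, labels, 1).set_index("feature_id")
        assert table.loc["expr_f7", "p_value"] == 1.0
        assert bool(table.loc["expr_f7", "constant"])

    def test_label_permutation_invariance(self, shifted_dataset):
        blocks, labels = shifted_dataset
        t1 = signature_features(blocks, labels, 1).set_index("feature_id")
        swapped = np.where(labels == 1, 9, 1)
        t2 = signature_features(blocks, swapped, 9).set_index("feature_id")
        assert np.allclose(
            t1["p_value"].sort_index(), t2["p_value"].sort_index(), atol=1e-12
        )

    def test_empty_cluster_rejected(self, shifted_dataset):
        blocks, labels = shifted_dataset
        with pytest.raises(ValueError, match="empty"):
            signature_features(blocks, labels, 3)
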