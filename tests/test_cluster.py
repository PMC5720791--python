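"""Pruning, assignment, the parallel merge, Kmeans baseline, quantification."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from xhclust import (
    ClusterMap,
    SpectralMatrix,
    assign,
    circular_roi_mask,
    grow_tree,
    kmeans_baseline,
    lloyd_kmeans,
    load_model,
    prune_to_k,
    quantify_clusters,
    save_model,
    xhc_parallel,
)
from xhclust.errors import ParameterError


def matrix_from(X, image_id=0):
    m, n = X.shape
    cols = int(np.ceil(np.sqrt(n)))
    index = [(image_id, j // cols, j % cols) for j in range(n)]
    return SpectralMatrix(X, index, 400.0 + np.arange(m, dtype=float))


class TestPruneToK:
    def test_l_equals_k_returns_leaf_means(self, rng):
        Y = rng.normal(size=(4, 6))
        model = prune_to_k(Y, k=4, seed=0)
        got = {tuple(np.round(r, 9)) for r in model.representatives}
        want = {tuple(np.round(r, 9)) for r in Y}
        assert got == want

    def test_k1_is_global_mean(self, rng):
        Y = rng.normal(size=(10, 5))
        model = prune_to_k(Y, k=1, seed=0)
        assert np.allclose(model.representatives[0], Y.mean(axis=0))

    def test_tight_blobs_recover_centers(self, rng):
        centers = np.array([[0.0] * 6, [5.0] * 6, [0.0] * 3 + [5.0] * 3,
                            [5.0] * 3 + [0.0] * 3])
        Y = np.vstack([c + rng.normal(0, 0.05, size=(20, 6)) for c in centers])
        model = prune_to_k(Y, k=4, seed=0)
        d = cdist(model.representatives, centers)
        assert np.all(d.min(axis=1) < 0.1)
        assert len(set(d.argmin(axis=1))) == 4

    def test_too_few_leaves_actionable_error(self, rng):
        with pytest.raises(ParameterError, match="deepen the tree"):
            prune_to_k(rng.normal(size=(3, 5)), k=7)

    def test_representative_order_canonical(self, rng):
        Y = rng.normal(size=(30, 6))
        m1 = prune_to_k(Y, k=4, seed=0)
        m2 = prune_to_k(Y[rng.permutation(30)], k=4, seed=0)
        assert np.allclose(m1.representatives, m2.representatives)
        means = m1.representatives.mean(axis=1)
        assert np.all(np.diff(means) >= 0)


class TestAssign:
    def test_representatives_assign_to_themselves(self, rng):
        reps = rng.normal(size=(5, 8))
        model = prune_to_k(reps, k=5, seed=0)
        labels = assign(model.representatives.T, model)
        assert list(labels) == [1, 2, 3, 4, 5]

    def test_equidistant_takes_lowest_index(self):
        reps = np.array([[0.0], [2.0], [4.0]])
        model = prune_to_k(reps, k=3, seed=0)
        # point at 1.0 is equidistant from reps 0.0 and 2.0
        labels = assign(np.array([[1.0]]), model)
        assert labels[0] == 1

    def test_matches_distance_table_oracle(self, rng):
        reps = rng.normal(size=(4, 10))
        model = prune_to_k(reps, k=4, seed=0)
        X = rng.normal(size=(10, 50))
        labels = assign(X, model)
        for j in range(50):
            dists = [np.linalg.norm(X[:, j] - r) for r in model.representatives]
            assert labels[j] == int(np.argmin(dists)) + 1

    def test_dimension_mismatch_rejected(self, rng):
        model = prune_to_k(rng.normal(size=(3, 5)), k=3, seed=0)
        with pytest.raises(ParameterError):
            assign(rng.normal(size=(4, 10)), model)

    def test_model_json_round_trip(self, rng, tmp_path):
        model = prune_to_k(rng.normal(size=(6, 5)), k=3, seed=0)
        save_model(model, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        assert np.allclose(back.representatives, model.representatives)
        assert back.k == model.k and back.variant == model.variant


class TestLloydKmeans:
    def test_k1_centroid_is_mean(self, rng):
        pts = rng.normal(size=(40, 6))
        _, centroids, _ = lloyd_kmeans(pts, 1, seed=0)
        assert np.allclose(centroids[0], pts.mean(axis=0))

    def test_duplicated_blobs_converge_fast(self, rng):
        centers = rng.normal(size=(3, 5)) * 10
        pts = np.repeat(centers, 15, axis=0)
        labels, centroids, iters = lloyd_kmeans(pts, 3, seed=0)
        assert iters <= 2
        d = cdist(centroids, centers)
        assert np.all(d.min(axis=1) < 1e-9)

    def test_inertia_non_increasing(self, rng):
        # re-run Lloyd manually and monitor within-cluster sum of squares
        pts = rng.normal(size=(200, 4))
        from xhclust.cluster import _farthest_point_init

        centroids = _farthest_point_init(pts, 5, np.random.default_rng(0))
        prev = np.inf
        for _ in range(20):
            d = cdist(pts, centroids)
            lab = d.argmin(axis=1)
            inertia = float((d[np.arange(len(pts)), lab] ** 2).sum())
            assert inertia <= prev + 1e-9
            prev = inertia
            for j in range(5):
                if np.any(lab == j):
                    centroids[j] = pts[lab == j].mean(axis=0)

    def test_concordant_with_sklearn_on_blobs(self, rng):
        centers = rng.normal(size=(4, 6)) * 8
        pts = np.vstack([c + rng.normal(0, 0.3, size=(50, 6)) for c in centers])
        ours, _, _ = lloyd_kmeans(pts, 4, seed=0)
        ref = KMeans(n_clusters=4, n_init=10, random_state=0).fit_predict(pts)
        assert adjusted_rand_score(ours, ref) >= 0.99

    def test_fewer_distinct_points_than_k(self):
        with pytest.raises(ParameterError):
            lloyd_kmeans(np.ones((10, 3)), 2, seed=0)


class TestKmeansBaseline:
    def test_labels_one_based_and_complete(self, rng):
        X = rng.normal(size=(5, 60))
        labels, centroids = kmeans_baseline(X, 3, seed=0)
        assert labels.min() >= 1 and labels.max() <= 3
        assert centroids.shape == (3, 5)


class TestXhcParallel:
    @pytest.fixture
    def blob_matrix(self, rng):
        centers = [np.zeros(6), np.full(6, 8.0), np.r_[np.full(3, -8.0), np.zeros(3)]]
        cols = np.hstack([c[:, None] + rng.normal(0, 0.2, size=(6, 120))
                          for c in centers])
        perm = rng.permutation(cols.shape[1])
        return matrix_from(cols[:, perm])

    def test_single_subset_equals_serial(self, blob_matrix):
        serial_tree = grow_tree(blob_matrix, min_leaf=15, seed=9)
        serial = prune_to_k(serial_tree, k=3, seed=9)
        parallel = xhc_parallel([blob_matrix], k=3, min_leaf=15, seed=9)
        assert np.array_equal(serial.representatives, parallel.representatives)

    def test_split_halves_agree_with_whole(self, blob_matrix, rng):
        n = blob_matrix.n_signatures
        h1 = SpectralMatrix(blob_matrix.X[:, :n // 2],
                            [("h1", r, c) for _, r, c in blob_matrix.pixel_index[:n // 2]],
                            blob_matrix.wavelengths)
        h2 = SpectralMatrix(blob_matrix.X[:, n // 2:],
                            [("h2", r, c) for _, r, c in blob_matrix.pixel_index[n // 2:]],
                            blob_matrix.wavelengths)
        whole = xhc_parallel([blob_matrix], k=3, min_leaf=15, seed=0)
        halves = xhc_parallel([h1, h2], k=3, min_leaf=15, seed=0)
        ari = adjusted_rand_score(assign(blob_matrix, whole),
                                  assign(blob_matrix, halves))
        assert ari >= 0.95

    def test_subset_order_irrelevant(self, blob_matrix):
        n = blob_matrix.n_signatures
        h1 = SpectralMatrix(blob_matrix.X[:, :n // 2],
                            [("h1", r, c) for _, r, c in blob_matrix.pixel_index[:n // 2]],
                            blob_matrix.wavelengths)
        h2 = SpectralMatrix(blob_matrix.X[:, n // 2:],
                            [("h2", r, c) for _, r, c in blob_matrix.pixel_index[n // 2:]],
                            blob_matrix.wavelengths)
        m12 = xhc_parallel([h1, h2], k=3, min_leaf=15, seed=1)
        m21 = xhc_parallel([h2, h1], k=3, min_leaf=15, seed=1)
        assert np.array_equal(m12.representatives, m21.representatives)

    def test_inconsistent_bands_rejected(self, blob_matrix, rng):
        other = matrix_from(rng.normal(size=(4, 50)))
        with pytest.raises(ParameterError):
            xhc_parallel([blob_matrix, other], k=2)


class TestQuantifyClusters:
    def test_counts_and_conservation(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:2, :5] = 3
        labels[5:, :] = 1
        cmap = ClusterMap(labels=labels, k=3)
        counts = quantify_clusters(cmap)
        assert counts[3] == 10
        assert counts[1] == 50
        assert counts["total"] == counts[1] + counts[2] + counts[3]

    def test_roi_can_exclude_a_cluster(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0, 0] = 3
        labels[5, 5] = 1
        cmap = ClusterMap(labels=labels, k=3)
        roi = circular_roi_mask((10, 10), (5, 5), 4)
        counts = quantify_clusters(cmap, roi)
        assert counts[3] == 0 and counts[1] == 1 and counts["total"] == 1
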