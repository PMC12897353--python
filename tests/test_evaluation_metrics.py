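import itertools
import math

import numpy as np
import pytest

from scirt.evaluation_metrics import (
    adjusted_rand_index,
    corr2,
    davies_bouldin_index,
    kmeans_cluster,
    normalized_mutual_information,
    silhouette_coefficient,
)
from scirt.expression_io import ValidationError


def brute_force_ari(a, b):
    """Pair-counting ARI over all C(n,2) pairs."""
    n = len(a)
    same_a = same_b = both = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        same_a += sa
        same_b += sb
        both += sa and sb
    total = math.comb(n, 2)
    expected = same_a * same_b / total
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 0.0
    return (both - expected) / (max_index - expected)


def brute_force_nmi(a, b):
    """I(A;B) / arithmetic mean of entropies, natural logs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)

    def entropy(x):
        _, counts = np.unique(x, return_counts=True)
        p = counts / n
        return -np.sum(p * np.log(p))

    mi = 0.0
    for ai in np.unique(a):
        for bi in np.unique(b):
            pij = np.mean((a == ai) & (b == bi))
            if pij > 0:
                mi += pij * np.log(pij / (np.mean(a == ai) * np.mean(b == bi)))
    denom = (entropy(a) + entropy(b)) / 2
    return mi / denom if denom > 0 else 1.0


def brute_force_silhouette(X, labels):
    X, labels = np.asarray(X, float), np.asarray(labels)
    n = len(labels)
    scores = []
    for i in range(n):
        own = labels == labels[i]
        dists = np.linalg.norm(X - X[i], axis=1)
        if own.sum() == 1:
            scores.append(0.0)
            continue
        a = dists[own & (np.arange(n) != i)].mean()
        b = min(dists[labels == lab].mean() for lab in np.unique(labels) if lab != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def brute_force_dbi(X, labels):
    X, labels = np.asarray(X, float), np.asarray(labels)
    labs = np.unique(labels)
    centroids = [X[labels == lab].mean(axis=0) for lab in labs]
    scatter = [
        np.mean(np.linalg.norm(X[labels == lab] - c, axis=1))
        for lab, c in zip(labs, centroids)
    ]
    total = 0.0
    for i in range(len(labs)):
        worst = max(
            (scatter[i] + scatter[j]) / np.linalg.norm(centroids[i] - centroids[j])
            for j in range(len(labs))
            if j != i
        )
        total += worst
    return total / len(labs)


class TestKmeans:
    def test_separable_clouds_perfectly_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(100, 0.1, (10, 3))])
        truth = [0] * 10 + [1] * 10
        result = kmeans_cluster(X, k=2, seed=0)
        assert adjusted_rand_index(truth, result.assignments) == 1.0

    def test_k_one_inertia_is_total_scatter(self, rng):
        X = rng.uniform(size=(15, 4))
        result = kmeans_cluster(X, k=1, seed=0)
        expected = np.sum((X - X.mean(axis=0)) ** 2)
        assert result.inertia == pytest.approx(expected, rel=1e-9)

    def test_same_seed_same_assignments(self, rng):
        X = rng.uniform(size=(30, 5))
        a = kmeans_cluster(X, k=3, seed=4).assignments
        b = kmeans_cluster(X, k=3, seed=4).assignments
        np.testing.assert_array_equal(a, b)

    def test_invalid_k(self, rng):
        with pytest.raises(ValidationError):
            kmeans_cluster(rng.uniform(size=(5, 2)), k=0)
        with pytest.raises(ValidationError):
            kmeans_cluster(rng.uniform(size=(5, 2)), k=6)


class TestAri:
    def test_identical_labelings(self):
        assert adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_single_cluster_vs_nontrivial_is_zero(self):
        assert adjusted_rand_index([0, 0, 0, 0], [0, 1, 2, 0]) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self):
        a, b = [0, 0, 1, 1], [0, 1, 1, 1]
        assert adjusted_rand_index(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-10)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, size=10)
            b = rng.integers(0, 3, size=10)
            assert adjusted_rand_index(a, b) == pytest.approx(
                brute_force_ari(list(a), list(b)), abs=1e-10
            )

    def test_symmetric_and_permutation_invariant(self, rng):
        a = rng.integers(0, 3, size=12)
        b = rng.integers(0, 4, size=12)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        remapped = (b + 7) % 4
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(a, remapped))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestNmi:
    def test_identical_labelings(self):
        assert normalized_mutual_information([0, 1, 0, 1], [5, 9, 5, 9]) == pytest.approx(1.0)

    def test_perfect_dependence_2x2(self):
        assert normalized_mutual_information([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_independent_labelings_near_zero(self, rng):
        vals = []
        for _ in range(200):
            a = rng.integers(0, 2, size=400)
            b = rng.integers(0, 2, size=400)
            vals.append(normalized_mutual_information(a, b))
        assert np.mean(vals) < 0.05

    def test_matches_contingency_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, size=10)
            b = rng.integers(0, 3, size=10)
            assert normalized_mutual_information(a, b) == pytest.approx(
                brute_force_nmi(a, b), abs=1e-10
            )


class TestSilhouette:
    def test_tight_separated_clusters_near_one(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (8, 2)), rng.normal(1000, 0.01, (8, 2))])
        labels = [0] * 8 + [1] * 8
        assert silhouette_coefficient(X, labels) > 0.999

    def test_random_labels_on_one_blob_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 4))
            labels = rng.integers(0, 2, size=60)
            vals.append(silhouette_coefficient(X, labels))
        assert abs(np.mean(vals)) < 0.1

    def test_matches_hand_computation_four_points(self):
        X = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        labels = [0, 0, 1, 1]
        assert silhouette_coefficient(X, labels) == pytest.approx(
            brute_force_silhouette(X, labels), abs=1e-10
        )

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(5):
            X = rng.uniform(size=(10, 3))
            labels = rng.integers(0, 3, size=10)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette_coefficient(X, labels) == pytest.approx(
                brute_force_silhouette(X, labels), abs=1e-10
            )

    def test_translation_and_rotation_invariant(self, rng):
        X = rng.uniform(size=(12, 2))
        labels = rng.integers(0, 2, size=12)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = X @ R.T + 42.0
        assert silhouette_coefficient(X, labels) == pytest.approx(
            silhouette_coefficient(moved, labels), abs=1e-9
        )

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValidationError):
            silhouette_coefficient(rng.uniform(size=(5, 2)), [0] * 5)


class TestDaviesBouldin:
    def test_well_separated_tight_clusters_near_zero(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (8, 2)), rng.normal(1000, 0.01, (8, 2))])
        assert davies_bouldin_index(X, [0] * 8 + [1] * 8) < 0.001

    def test_duplicated_dataset_invariance(self, rng):
        X = rng.uniform(size=(9, 3))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        doubled_X = np.vstack([X, X])
        doubled_labels = np.concatenate([labels, labels])
        assert davies_bouldin_index(X, labels) == pytest.approx(
            davies_bouldin_index(doubled_X, doubled_labels), rel=1e-9
        )

    def test_matches_hand_computation(self, rng):
        X = rng.uniform(size=(6, 2))
        labels = [0, 0, 1, 1, 2, 2]
        assert davies_bouldin_index(X, labels) == pytest.approx(
            brute_force_dbi(X, labels), abs=1e-10
        )

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import davies_bouldin_score

        X = rng.uniform(size=(20, 4))
        labels = rng.integers(0, 3, size=20)
        assert davies_bouldin_index(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels), abs=1e-9
        )

    def test_coincident_centroids_guarded(self):
        X = np.array([[0.0, 0], [2, 0], [0, 0], [2, 0]])
        labels = [0, 0, 1, 1]  # identical centroids
        value = davies_bouldin_index(X, labels)
        assert np.isfinite(value)


class TestCorr2:
    def test_self_correlation_is_one(self, rng):
        A = rng.uniform(size=(4, 5))
        assert corr2(A, A) == pytest.approx(1.0)

    def test_positive_affine_invariance(self, rng):
        A = rng.uniform(size=(4, 5))
        assert corr2(A, 3.2 * A + 1.5) == pytest.approx(1.0)

    def test_matches_flattened_pearson_oracle(self):
        from scipy.stats import pearsonr

        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        B = np.array([[1.0, 2.0], [4.0, 3.0]])
        expected = pearsonr(A.ravel(), B.ravel()).statistic
        assert corr2(A, B) == pytest.approx(expected, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            corr2(np.ones((2, 2)), np.array([[1.0, 2.0], [3.0, 4.0]]))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            corr2(rng.uniform(size=(2, 3)), rng.uniform(size=(3, 2)))
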