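"""k-medoids, agglomerative, DBSCAN, silhouette widths, optimal-k selection."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from shapeclust.clustering import (DEFAULT_K_RANGE, Clustering, agglomerative,
                                   dbscan, k_medoids, select_k, silhouette)


def _blob_matrix(sizes, gap=1.0, rng=None, jitter=0.0):
    """Block matrix: zero (or small) within blocks, `gap` across blocks."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    v = np.where(labels[:, None] == labels[None, :], 0.0, gap)
    if jitter and rng is not None:
        noise = rng.uniform(0, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        v = v + noise
    np.fill_diagonal(v, 0.0)
    return v, labels


def _exhaustive_kmedoids_cost(values, k):
    """Minimal assignment cost over all medoid subsets (brute force)."""
    n = len(values)
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = values[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestKMedoids:
    def test_two_blobs_exact_partition(self):
        v, labels = _blob_matrix([4, 4])
        c = k_medoids(v, 2, seed=0)
        assert len(set(zip(c.labels, labels))) == 2  # one-to-one mapping
        assert c.params["cost"] == pytest.approx(
            _exhaustive_kmedoids_cost(v, 2))

    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_matches_exhaustive_search_on_small_random(self, seed, k):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.2, 1.0, size=(8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        c = k_medoids(v, k, seed=42, restarts=10)
        assert c.params["cost"] == pytest.approx(
            _exhaustive_kmedoids_cost(v, k), abs=1e-12)

    def test_k_equals_n_minus_one_leaves_one_pair(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, size=(6, 2))
        v = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c = k_medoids(v, 5, seed=0, restarts=20)
        sizes = sorted(np.bincount(c.labels))
        assert sizes == [1, 1, 1, 1, 2]
        assert c.params["cost"] == pytest.approx(
            _exhaustive_kmedoids_cost(v, 5), abs=1e-12)

    def test_k_out_of_range_errors(self):
        v, _ = _blob_matrix([3, 3])
        with pytest.raises(ValueError, match="k must be"):
            k_medoids(v, 6)
        with pytest.raises(ValueError, match="k must be"):
            k_medoids(v, 1)

    def test_objective_non_increasing_within_restart(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(0.2, 1.0, size=(20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        _, history = k_medoids(v, 4, seed=7, restarts=5, return_history=True)
        for run in history:
            assert all(b <= a + 1e-12 for a, b in zip(run, run[1:]))

    def test_deterministic_given_seed(self):
        v, _ = _blob_matrix([5, 5], jitter=0.2, rng=np.random.default_rng(0))
        a = k_medoids(v, 2, seed=3)
        b = k_medoids(v, 2, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAgglomerative:
    def test_cut_at_n_gives_singletons(self):
        v, _ = _blob_matrix([3, 3])
        c = agglomerative(v, 6)
        assert c.n_clusters == 6

    def test_cut_at_one_gives_single_cluster(self):
        v, _ = _blob_matrix([3, 3])
        assert agglomerative(v, 1).n_clusters == 1

    def test_two_tight_pairs(self):
        # four points: two tight pairs far apart
        v = np.array([
            [0.0, 0.1, 5.0, 5.2],
            [0.1, 0.0, 5.1, 5.0],
            [5.0, 5.1, 0.0, 0.2],
            [5.2, 5.0, 0.2, 0.0],
        ])
        c = agglomerative(v, 2)
        assert c.labels[0] == c.labels[1]
        assert c.labels[2] == c.labels[3]
        assert c.labels[0] != c.labels[2]


class TestDbscan:
    def test_single_tight_blob(self):
        v, _ = _blob_matrix([6], gap=0.0)
        v += 0.01 * (1 - np.eye(6))
        c = dbscan(v, eps=0.5, min_pts=3)
        assert c.n_clusters == 1

    def test_two_blobs_with_gap(self):
        v, labels = _blob_matrix([5, 5], gap=10.0)
        v += 0.01 * (1 - np.eye(10))
        c = dbscan(v, eps=1.0, min_pts=3)
        assert c.n_clusters == 2
        assert len(set(zip(c.labels, labels))) == 2

    def test_all_far_apart_becomes_singletons(self):
        v = 10.0 * (1 - np.eye(5))
        c = dbscan(v, eps=1.0, min_pts=2)
        assert c.n_clusters == 5  # every point is noise -> singleton

    def test_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(2)
        v, _ = _blob_matrix([4, 4], gap=10.0, rng=rng, jitter=0.05)
        perm = rng.permutation(8)
        c1 = dbscan(v, eps=1.0, min_pts=3)
        c2 = dbscan(v[np.ix_(perm, perm)], eps=1.0, min_pts=3)
        # compare partitions as sets of frozensets of original indices
        def groups(labels, order):
            out = {}
            for pos, l in enumerate(labels):
                out.setdefault(l, set()).add(int(order[pos]))
            return {frozenset(s) for s in out.values()}
        assert groups(c1.labels, np.arange(8)) == groups(c2.labels, perm)


class TestSilhouette:
    def test_two_zero_diameter_clusters_all_ones(self):
        v, labels = _blob_matrix([5, 5])
        c = Clustering(ids=[str(i) for i in range(10)], labels=labels)
        prof = silhouette(v, c)
        np.testing.assert_allclose(prof.s_values, 1.0)
        assert prof.average == 1.0

    def test_equidistant_object_scores_zero(self):
        # object 0 at distance 1 from both its own partner and the others
        v = np.array([
            [0.0, 1.0, 1.0, 1.0],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.1],
            [1.0, 1.0, 0.1, 0.0],
        ])
        c = Clustering(ids=list("abcd"), labels=np.array([0, 0, 1, 1]))
        prof = silhouette(v, c)
        assert prof.s_values[0] == pytest.approx(0.0)

    def test_hand_computed_four_point_fixture(self):
        v = np.array([
            [0.0, 1.0, 4.0, 5.0],
            [1.0, 0.0, 3.0, 4.0],
            [4.0, 3.0, 0.0, 2.0],
            [5.0, 4.0, 2.0, 0.0],
        ])
        c = Clustering(ids=list("abcd"), labels=np.array([0, 0, 1, 1]))
        prof = silhouette(v, c)
        expected = [3.5 / 4.5, 2.5 / 3.5, 1.5 / 3.5, 2.5 / 4.5]
        np.testing.assert_allclose(prof.s_values, expected, atol=1e-12)

    def test_singleton_cluster_scores_zero(self):
        v, _ = _blob_matrix([3, 1])
        c = Clustering(ids=list("abcd"), labels=np.array([0, 0, 0, 1]))
        prof = silhouette(v, c)
        assert prof.s_values[3] == 0.0

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.1, 2.0, size=(15, 15))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = rng.integers(0, 3, size=15)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 3, size=15)
        c = Clustering(ids=[str(i) for i in range(15)], labels=labels)
        prof = silhouette(v, c)
        ref = silhouette_samples(v, labels, metric="precomputed")
        np.testing.assert_allclose(prof.s_values, ref, atol=1e-12)

    def test_single_cluster_errors(self):
        v, _ = _blob_matrix([4])
        c = Clustering(ids=list("abcd"), labels=np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="single cluster"):
            silhouette(v, c)

    def test_range_bounds_on_random_data(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.1, 3.0, size=(20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        c = Clustering(ids=[str(i) for i in range(20)],
                       labels=rng.integers(0, 4, size=20))
        prof = silhouette(v, c)
        assert np.all(prof.s_values >= -1) and np.all(prof.s_values <= 1)


class TestSelectK:
    def test_three_separated_families_select_three(self):
        rng = np.random.default_rng(6)
        v, _ = _blob_matrix([5, 5, 5], gap=1.0, rng=rng, jitter=0.05)
        k_star, c, prof = select_k(v, k_range=range(2, 7), seed=0)
        assert k_star == 3
        assert c.n_clusters == 3
        assert set(prof.per_k) == {2, 3, 4, 5, 6}

    def test_two_zero_diameter_clusters(self):
        v, _ = _blob_matrix([4, 4])
        k_star, _, prof = select_k(v, k_range=range(2, 5), seed=0)
        assert k_star == 2
        assert prof.average == pytest.approx(1.0)

    def test_default_range_is_3_to_25(self):
        assert list(DEFAULT_K_RANGE) == list(range(3, 26))
        rng = np.random.default_rng(0)
        v, _ = _blob_matrix([10, 10, 10], gap=1.0, rng=rng, jitter=0.05)
        k_star, _, prof = select_k(v, seed=0)  # k_range omitted
        assert min(prof.per_k) == 3 and max(prof.per_k) == 25

    def test_empty_effective_range_errors(self):
        v, _ = _blob_matrix([2, 1])
        with pytest.raises(ValueError, match="no feasible k"):
            select_k(v, k_range=range(10, 12))
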