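"""k-means correctness against brute force and validity-index oracles."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans as SKKMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

from igeprofile.clustering import (
    ClusteringConfig,
    euclidean_distance,
    kmeans,
    select_k,
    validity_indices,
)


def brute_force_min_wcss(X, k):
    """Exhaustive minimum-WCSS partition over all surjective assignments."""
    n = len(X)
    best_wcss, best_labels = np.inf, None
    for assignment in itertools.product(range(k), repeat=n):
        labels = np.array(assignment)
        if len(set(assignment)) < k:
            continue
        wcss = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
            for c in range(k)
        )
        if wcss < best_wcss:
            best_wcss, best_labels = wcss, labels
    return best_wcss, best_labels


def reference_indices(X, labels, q=3):
    """Independent direct-formula validity indices, plain loops throughout."""
    n = len(X)
    D = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    clusters = sorted(set(labels))

    sil = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            sil.append(0.0)
            continue
        a = np.mean([D[i][j] for j in own])
        b = min(np.mean([D[i][j] for j in range(n) if labels[j] == c])
                for c in clusters if c != labels[i])
        sil.append((b - a) / max(a, b))
    silhouette = float(np.mean(sil))

    diam = max(max(D[i][j] for i in range(n) for j in range(n)
                   if labels[i] == labels[j] == c) for c in clusters)
    sep = min(D[i][j] for i in range(n) for j in range(n)
              if labels[i] != labels[j])
    dunn = sep / diam

    cents = {c: X[[i for i in range(n) if labels[i] == c]].mean(axis=0) for c in clusters}
    s = {c: np.mean([np.linalg.norm(X[i] - cents[c])
                     for i in range(n) if labels[i] == c]) for c in clusters}
    db = np.mean([max((s[c1] + s[c2]) / np.linalg.norm(cents[c1] - cents[c2])
                      for c2 in clusters if c2 != c1) for c1 in clusters])

    within = [D[i][j] for i in range(n) for j in range(i + 1, n)
              if labels[i] == labels[j]]
    alld = sorted(D[i][j] for i in range(n) for j in range(i + 1, n))
    nw = len(within)
    c_index = (sum(within) - sum(alld[:nw])) / (sum(alld[-nw:]) - sum(alld[:nw]))

    iso = []
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: D[i][j])[:q]
        iso.append(np.mean([labels[j] == labels[i] for j in order]))
    isolation = float(np.mean(iso))
    return {"silhouette": silhouette, "dunn": dunn, "davies_bouldin": db,
            "c_index": c_index, "isolation": isolation}


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "u,v,expected",
        [([0, 0, 0], [0, 0, 0], 0.0), ([0, 3], [4, 0], 5.0),
         ([1, 1, 1, 1], [2, 2, 2, 2], 2.0)],
    )
    def test_examples(self, u, v, expected):
        assert euclidean_distance(u, v) == pytest.approx(expected)
        assert euclidean_distance(v, u) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestKmeans:
    def test_duplicated_points_recover_exactly(self):
        X = np.array([[0.0, 0.0]] * 4 + [[5.0, 5.0]] * 4)
        result = kmeans(X, 2, ClusteringConfig(seed=0, n_restarts=5))
        assert result.wcss == pytest.approx(0.0)
        assert {tuple(c) for c in result.centroids} == {(0.0, 0.0), (5.0, 5.0)}

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        result = kmeans(X, 6, ClusteringConfig(seed=1, n_restarts=10))
        assert result.wcss == pytest.approx(0.0, abs=1e-12)
        assert len(set(result.assignments)) == 6

    @pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (7, 2, 1), (8, 3, 2), (6, 3, 3)])
    def test_matches_brute_force_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        best_wcss, _ = brute_force_min_wcss(X, k)
        result = kmeans(X, k, ClusteringConfig(seed=seed, n_restarts=50))
        assert result.wcss == pytest.approx(best_wcss, rel=1e-9)

    def test_wcss_definition_holds(self, three_blob_data):
        result = kmeans(three_blob_data, 3, ClusteringConfig(seed=0))
        manual = sum(
            euclidean_distance(x, result.centroids[c]) ** 2
            for x, c in zip(three_blob_data, result.assignments)
        )
        assert result.wcss == pytest.approx(manual)

    def test_agrees_with_sklearn_on_blobs(self, three_blob_data):
        ours = kmeans(three_blob_data, 3, ClusteringConfig(seed=0))
        sk = SKKMeans(n_clusters=3, n_init=10, random_state=0).fit(three_blob_data)
        assert ours.wcss == pytest.approx(sk.inertia_, rel=1e-6)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), 4)

    def test_deterministic_for_fixed_seed(self, three_blob_data):
        a = kmeans(three_blob_data, 3, ClusteringConfig(seed=5))
        b = kmeans(three_blob_data, 3, ClusteringConfig(seed=5))
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestValidityIndices:
    def test_two_tight_separated_clusters(self):
        # clusters larger than the q=10 neighbourhood so isolation can reach 1
        X = np.array([[0.0, 0.0]] * 11 + [[9.0, 9.0]] * 11)
        result = kmeans(X, 2, ClusteringConfig(seed=0))
        idx = validity_indices(X, result)
        assert idx["silhouette"] == pytest.approx(1.0)
        assert idx["davies_bouldin"] == pytest.approx(0.0)
        assert idx["isolation"] == pytest.approx(1.0)
        assert idx["c_index"] == pytest.approx(0.0)

    def test_random_labels_on_one_cloud_give_null_silhouette(self):
        values = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 4))
            labels = rng.integers(0, 3, size=200)
            from igeprofile.clustering import ClusterResult

            result = ClusterResult(3, labels,
                                   np.array([X[labels == c].mean(axis=0)
                                             for c in range(3)]), 0.0, True, 1)
            values.append(validity_indices(X, result)["silhouette"])
        assert all(abs(v) < 0.1 for v in values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_eight_point_fixture_matches_reference_loops(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        result = kmeans(X, 3, ClusteringConfig(seed=seed, n_restarts=30,
                                               isolation_q=3))
        ours = validity_indices(X, result, q=3)
        ref = reference_indices(X, result.assignments, q=3)
        for key in ref:
            assert ours[key] == pytest.approx(ref[key], rel=1e-9), key

    def test_silhouette_and_db_match_sklearn(self, three_blob_data):
        result = kmeans(three_blob_data, 3, ClusteringConfig(seed=0))
        ours = validity_indices(three_blob_data, result)
        assert ours["silhouette"] == pytest.approx(
            silhouette_score(three_blob_data, result.assignments), rel=1e-9)
        assert ours["davies_bouldin"] == pytest.approx(
            davies_bouldin_score(three_blob_data, result.assignments), rel=1e-9)

    def test_indices_invariant_to_relabeling_and_reordering(self, three_blob_data):
        from igeprofile.clustering import ClusterResult

        result = kmeans(three_blob_data, 3, ClusteringConfig(seed=0))
        base = validity_indices(three_blob_data, result)

        relabel = np.array([2, 0, 1])[result.assignments]
        cents = np.array([three_blob_data[relabel == c].mean(axis=0) for c in range(3)])
        permuted = validity_indices(
            three_blob_data, ClusterResult(3, relabel, cents, result.wcss, True, 1))
        for key in base:
            assert base[key] == pytest.approx(permuted[key])

        rng = np.random.default_rng(4)
        order = rng.permutation(len(three_blob_data))
        reordered = validity_indices(
            three_blob_data[order],
            ClusterResult(3, result.assignments[order],
                          result.centroids, result.wcss, True, 1))
        for key in base:
            assert base[key] == pytest.approx(reordered[key])


class TestSelectK:
    def test_recovers_three_planted_clusters(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(c, 0.5, size=(25, 4)) for c in (0, 5, 10)])
            report = select_k(X, ClusteringConfig(k_candidates=tuple(range(2, 7)),
                                                  n_restarts=10, seed=seed))
            hits += report.chosen_k == 3
        assert hits >= 9

    def test_single_candidate_returned(self, three_blob_data):
        report = select_k(three_blob_data, ClusteringConfig(k_candidates=(2,), seed=0))
        assert report.chosen_k == 2

    def test_duplicate_candidates_collapse(self):
        X = np.array([[0.0, 0.0]] * 6 + [[9.0, 9.0]] * 6 + [[0.0, 9.0]] * 6)
        report = select_k(X, ClusteringConfig(k_candidates=(3, 3), seed=0))
        assert report.chosen_k == 3

    def test_vote_tie_breaks_by_mean_rank_then_smaller_k(self):
        # two clouds: k=2 is right; higher k splits a cloud and loses most
        # indices, and with candidates {2, 3} any split vote must resolve
        # deterministically to a single k
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, size=(20, 3)), rng.normal(6, 0.5, size=(20, 3))])
        report = select_k(X, ClusteringConfig(k_candidates=(2, 3), seed=1))
        assert report.chosen_k == 2

    def test_k_one_rejected_by_config(self):
        with pytest.raises(ValueError):
            ClusteringConfig(k_candidates=(1, 2, 3))
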