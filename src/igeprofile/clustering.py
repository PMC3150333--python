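"""k-means profile clustering and the five-index cluster-validity ensemble.

Reactivity profiles (one 0–5 class-score vector per subject across the
allergen panel) are grouped by Lloyd's k-means under Euclidean distance.
Because k is user-defined, candidate values are scored with five validity
indicators — Silhouette, Dunn, Davies-Bouldin, C-index and a
neighbour-purity Isolation index — and the number of clusters is chosen
by a plurality vote of the indices.

Index conventions (cohesion vs separation; higher-better marked ↑):

* Silhouette ↑ — mean over points of (b−a)/max(a,b), a = mean distance to
  own cluster, b = smallest mean distance to another cluster; singleton
  clusters score 0.
* Dunn ↑ — minimum between-cluster single-linkage distance divided by the
  maximum cluster diameter.
* Davies-Bouldin ↓ — mean over clusters of the worst (sᵢ+sⱼ)/d(cᵢ,cⱼ)
  ratio, s = mean distance to own centroid.
* C-index ↓ — (S − S_min)/(S_max − S_min), S = sum of within-cluster
  pairwise distances, S_min/S_max = sums of the equally many smallest and
  largest pairwise distances overall.
* Isolation ↑ — mean fraction of each point's q nearest neighbours that
  share its cluster (q defaults to 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass
class ClusteringConfig:
    k_candidates: tuple[int, ...] = tuple(range(2, 11))
    max_iterations: int = 10_000
    n_restarts: int = 25
    seed: int = 0
    isolation_q: int = 10

    def __post_init__(self) -> None:
        if any(k < 2 for k in self.k_candidates):
            raise ValueError("validity indices need k >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    wcss: float
    converged: bool
    iterations_used: int
    empty_cluster_reseeds: int = 0


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    """√Σ(uᵢ−vᵢ)² between two profile vectors of equal length."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def _wcss(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def _lloyd(X: np.ndarray, k: int, max_iterations: int,
           rng: np.random.Generator) -> ClusterResult:
    n = X.shape[0]
    seeds = rng.choice(n, size=k, replace=False)
    centroids = X[seeds].copy()
    labels = np.full(n, -1, dtype=int)
    reseeds = 0
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        dist = cdist(X, centroids)
        new_labels = np.argmin(dist, axis=1)
        # empty-cluster rescue: re-seed at the point farthest from its centroid
        if len(np.unique(new_labels)) < k:
            d_own = dist[np.arange(n), new_labels].copy()
            for c in range(k):
                if not (new_labels == c).any():
                    farthest = int(np.argmax(d_own))
                    new_labels[farthest] = c
                    centroids[c] = X[farthest]
                    d_own[farthest] = -np.inf
                    reseeds += 1
        if (new_labels == labels).all():
            converged = True
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if members.any():
                centroids[c] = X[members].mean(axis=0)
    return ClusterResult(k, labels, centroids, _wcss(X, labels, centroids),
                         converged, it, reseeds)


def kmeans(X: np.ndarray, k: int, config: ClusteringConfig | None = None) -> ClusterResult:
    """Best-of-restarts Lloyd k-means, deterministic for a fixed seed.

    Initial centroids are k distinct subjects drawn uniformly; the restart
    with the smallest within-cluster sum of squares is returned.
    """
    config = config or ClusteringConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(config.seed)
    best: ClusterResult | None = None
    for _ in range(config.n_restarts):
        result = _lloyd(X, k, config.max_iterations, rng)
        if best is None or result.wcss < best.wcss - 1e-12:
            best = result
    assert best is not None
    return best


def _silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            s[i] = 0.0  # singleton-cluster convention
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    diameters = [D[np.ix_(labels == c, labels == c)].max() for c in uniq]
    min_between = min(
        D[np.ix_(labels == c1, labels == c2)].min()
        for a, c1 in enumerate(uniq) for c2 in uniq[a + 1:]
    )
    max_diam = max(diameters)
    return float("inf") if max_diam == 0 else float(min_between / max_diam)


def _davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    centroids = np.array([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array([
        cdist(X[labels == c], centroids[m:m + 1]).mean()
        for m, c in enumerate(uniq)
    ])
    sep = cdist(centroids, centroids)
    if np.any((sep == 0) & ~np.eye(len(uniq), dtype=bool)):
        raise ValueError("coincident centroids: Davies-Bouldin undefined")
    ratios = []
    for i in range(len(uniq)):
        ratios.append(max(
            (scatter[i] + scatter[j]) / sep[i, j]
            for j in range(len(uniq)) if j != i
        ))
    return float(np.mean(ratios))


def _c_index(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    all_d = D[iu]
    within_mask = labels[iu[0]] == labels[iu[1]]
    n_within = int(within_mask.sum())
    if n_within == 0:
        return 0.0
    S = all_d[within_mask].sum()
    d_sorted = np.sort(all_d)
    s_min = d_sorted[:n_within].sum()
    s_max = d_sorted[-n_within:].sum()
    if s_max == s_min:
        return 0.0
    return float((S - s_min) / (s_max - s_min))


def _isolation(D: np.ndarray, labels: np.ndarray, q: int) -> float:
    n = len(labels)
    q = min(q, n - 1)
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    neighbours = np.argsort(D, axis=1, kind="stable")[:, :q]
    same = labels[neighbours] == labels[:, None]
    return float(same.mean())


@dataclass
class ValidityReport:
    table: pd.DataFrame  # one row per k: silhouette, dunn, davies_bouldin, c_index, isolation
    chosen_k: int
    votes: dict[int, int]
    rank_table: pd.DataFrame


#: direction of preference per index: True = larger is better
INDEX_DIRECTIONS = {
    "silhouette": True,
    "dunn": True,
    "davies_bouldin": False,
    "c_index": False,
    "isolation": True,
}


def validity_indices(X: np.ndarray, result: ClusterResult, q: int = 10) -> dict[str, float]:
    """All five validity indices for one clustering solution."""
    X = np.asarray(X, dtype=float)
    labels = result.assignments
    if len(np.unique(labels)) < 2:
        raise ValueError("validity indices need at least 2 non-empty clusters")
    D = squareform(pdist(X))
    return {
        "silhouette": _silhouette(D, labels),
        "dunn": _dunn(D, labels),
        "davies_bouldin": _davies_bouldin(X, labels),
        "c_index": _c_index(D, labels),
        "isolation": _isolation(D, labels, q),
    }


def select_k(X: np.ndarray, config: ClusteringConfig | None = None) -> ValidityReport:
    """Choose the number of clusters by plurality vote of the five indices.

    Each index votes for its best k (max for Silhouette/Dunn/Isolation,
    min for Davies-Bouldin/C-index); ties in the vote are broken by mean
    rank across indices, then by the smaller k.
    """
    config = config or ClusteringConfig()
    if len(config.k_candidates) < 2:
        if len(config.k_candidates) == 1:
            k = config.k_candidates[0]
            result = kmeans(X, k, config)
            row = validity_indices(X, result, config.isolation_q)
            table = pd.DataFrame([row], index=[k])
            return ValidityReport(table, k, {k: len(INDEX_DIRECTIONS)},
                                  table.rank())
        raise ValueError("need at least one candidate k")

    rows = {}
    for k in config.k_candidates:
        result = kmeans(X, k, config)
        try:
            rows[k] = validity_indices(X, result, config.isolation_q)
        except ValueError:
            continue  # degenerate solution at this k
    if not rows:
        raise ValueError("all candidate clusterings degenerate")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    ranks = pd.DataFrame(index=table.index)
    votes: dict[int, int] = {k: 0 for k in table.index}
    for index, larger_better in INDEX_DIRECTIONS.items():
        col = table[index]
        ranks[index] = col.rank(ascending=not larger_better, method="average")
        best_k = int((col.idxmax() if larger_better else col.idxmin()))
        votes[best_k] += 1
    max_votes = max(votes.values())
    tied = sorted(k for k, v in votes.items() if v == max_votes)
    if len(tied) > 1:
        mean_rank = ranks.loc[tied].mean(axis=1)
        tied = sorted(mean_rank.index[mean_rank == mean_rank.min()])
    chosen = int(tied[0])
    return ValidityReport(table, chosen, votes, ranks)
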