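"""Distance-matrix clustering, silhouette widths, and optimal-k selection.

All three methods operate directly on a precomputed distance matrix — no
vector embedding of the proteins is ever formed:

* k-medoids: PAM-style alternation of nearest-medoid assignment and
  medoid update (the member with the smallest sum of within-cluster
  distances), best of several random restarts.
* agglomerative: average-linkage hierarchical merging (scipy), cut at k.
* DBSCAN: density-based expansion (scikit-learn, precomputed metric); noise
  points are relabelled as fresh singleton clusters so that downstream
  silhouette and Rand computations stay well defined.

The silhouette width of object i is s_i = (b_i - a_i) / max(a_i, b_i), where
a_i is the mean distance to its own cluster's other members and b_i the
smallest mean distance to another cluster; members of singleton clusters get
s_i = 0. The number of clusters is selected by maximizing the average
silhouette width over a range of k (default 3..25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN

__all__ = [
    "Clustering",
    "SilhouetteProfile",
    "k_medoids",
    "agglomerative",
    "dbscan",
    "silhouette",
    "select_k",
    "DEFAULT_K_RANGE",
]

DEFAULT_K_RANGE = range(3, 26)  # "3 up to 25"


@dataclass
class Clustering:
    ids: list[str]
    labels: np.ndarray  # one integer label per id
    method: str = ""
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()))

    def validate(self) -> None:
        if len(self.labels) != len(self.ids):
            raise ValueError("labels and ids differ in length")
        if self.n_clusters < 1:
            raise ValueError("clustering has no clusters")


@dataclass
class SilhouetteProfile:
    s_values: np.ndarray  # per-object widths, each in [-1, 1]
    average: float
    per_k: dict[int, float] | None = None  # k -> average width (for select_k)

    def validate(self) -> None:
        if np.any(self.s_values < -1 - 1e-12) or np.any(self.s_values > 1 + 1e-12):
            raise ValueError("silhouette widths outside [-1, 1]")


def _matrix_values(matrix) -> tuple[np.ndarray, list[str]]:
    """Accept a DistanceMatrix or a raw symmetric array."""
    if hasattr(matrix, "values") and hasattr(matrix, "ids"):
        return np.asarray(matrix.values, dtype=float), list(matrix.ids)
    values = np.asarray(matrix, dtype=float)
    return values, [str(i) for i in range(len(values))]


def _swap_phase(values: np.ndarray, medoids: np.ndarray, history: list,
                max_swaps: int = 200) -> np.ndarray:
    """PAM swap improvement: replace a medoid by a non-medoid while it helps."""
    n = len(values)
    for _ in range(max_swaps):
        dist_to_med = values[:, medoids]
        order = np.argsort(dist_to_med, axis=1)
        nearest = order[:, 0]
        d1 = dist_to_med[np.arange(n), nearest]
        d2 = dist_to_med[np.arange(n), order[:, 1]]
        current = d1.sum()
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        best = (current - 1e-12, None, None)
        for i in range(len(medoids)):
            # cost of serving each object if medoid i is removed
            base = np.where(nearest == i, d2, d1)
            costs = np.minimum(base[:, None], values[:, non_medoids]).sum(axis=0)
            j = int(np.argmin(costs))
            if costs[j] < best[0]:
                best = (costs[j], i, non_medoids[j])
        if best[1] is None:
            break
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)
        history.append(float(best[0]))
    return medoids


def k_medoids(matrix, k: int, seed: int = 42, restarts: int = 10,
              max_iter: int = 300, return_history: bool = False) -> Clustering:
    """PAM-style k-medoids on a distance matrix, best of random restarts.

    Each restart alternates nearest-medoid assignment with the medoid update
    (member with the smallest sum of within-cluster distances) until stable,
    then applies PAM swap improvements. Deterministic given the seed; ties
    are broken by the lowest object index. The total distance to the medoids
    never increases across iterations within a restart.
    """
    values, ids = _matrix_values(matrix)
    n = len(values)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, n-1] = [2, {n - 1}], got {k}")
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_assign = None
    best_medoids = None
    history = []
    for _ in range(restarts):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        run_history = []
        for _ in range(max_iter):
            # Nearest-medoid assignment; argmin ties resolve to the medoid
            # with the lowest index (medoids are kept sorted).
            assign = np.argmin(values[:, medoids], axis=1)
            run_history.append(values[np.arange(n), medoids[assign]].sum())
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(assign == c)
                if members.size == 0:
                    continue  # keep the old medoid for an emptied cluster
                sums = values[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[int(np.argmin(sums))]
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        medoids = _swap_phase(values, medoids, run_history)
        assign = np.argmin(values[:, medoids], axis=1)
        cost = values[np.arange(n), medoids[assign]].sum()
        run_history.append(cost)
        history.append(run_history)
        if cost < best_cost - 1e-12:
            best_cost, best_assign, best_medoids = cost, assign, medoids
    result = Clustering(ids=ids, labels=best_assign.astype(int),
                        method="kmedoids",
                        params={"k": k, "restarts": restarts,
                                "medoids": best_medoids.tolist(),
                                "cost": float(best_cost)},
                        seed=seed)
    result.validate()
    if return_history:
        return result, history
    return result


def agglomerative(matrix, k: int) -> Clustering:
    """Average-linkage hierarchical clustering cut to k clusters."""
    values, ids = _matrix_values(matrix)
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n] = [1, {n}], got {k}")
    if n == 1 or k == n:
        labels = np.arange(n)
    else:
        Z = linkage(squareform(values, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    result = Clustering(ids=ids, labels=labels.astype(int),
                        method="agglomerative", params={"k": k})
    result.validate()
    return result


def dbscan(matrix, eps: float | None = None, min_pts: int = 4) -> Clustering:
    """Density-based clustering; noise points become fresh singleton clusters.

    Default eps is the 25th percentile of the off-diagonal distances.
    """
    values, ids = _matrix_values(matrix)
    n = len(values)
    if eps is None:
        off = values[~np.eye(n, dtype=bool)]
        eps = float(np.percentile(off, 25))
        if eps <= 0:
            eps = max(float(off.max()), 1e-12)
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    raw = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(values)
    labels = raw.labels_.copy()
    next_label = labels.max() + 1 if labels.max() >= 0 else 0
    for i in range(n):
        if labels[i] == -1:
            labels[i] = next_label
            next_label += 1
    result = Clustering(ids=ids, labels=labels.astype(int), method="dbscan",
                        params={"eps": eps, "min_pts": min_pts})
    result.validate()
    return result


def silhouette(matrix, clustering: Clustering) -> SilhouetteProfile:
    """Per-object and average silhouette widths of a clustering."""
    values, _ = _matrix_values(matrix)
    labels = np.asarray(clustering.labels)
    unique = np.unique(labels)
    if len(unique) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    n = len(values)
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in unique}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0  # singleton convention
            continue
        a_i = values[i, own[own != i]].mean()
        b_i = min(values[i, members[c]].mean() for c in unique if c != labels[i])
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    profile = SilhouetteProfile(s_values=s, average=float(s.mean()))
    profile.validate()
    return profile


def select_k(matrix, method: str = "kmedoids", k_range=None,
             seed: int = 42, restarts: int = 10):
    """Cluster at every k in the range and keep the best average silhouette.

    Returns (k_star, Clustering, SilhouetteProfile); the profile carries the
    per-k table of average widths. Ties go to the smallest k.
    """
    values, _ = _matrix_values(matrix)
    n = len(values)
    if k_range is None:
        k_range = DEFAULT_K_RANGE
    effective = [k for k in k_range if 2 <= k <= n - 1]
    if not effective:
        raise ValueError("no feasible k in the requested range")
    per_k: dict[int, float] = {}
    best = None
    for k in effective:
        if method == "kmedoids":
            c = k_medoids(matrix, k, seed=seed, restarts=restarts)
        elif method == "agglomerative":
            c = agglomerative(matrix, k)
        else:
            raise ValueError(
                f"select_k supports kmedoids and agglomerative, got {method!r}"
            )
        prof = silhouette(matrix, c)
        per_k[k] = prof.average
        if best is None or prof.average > best[2].average:
            best = (k, c, prof)
    k_star, clustering_, profile = best
    profile = SilhouetteProfile(s_values=profile.s_values,
                                average=profile.average, per_k=per_k)
    return k_star, clustering_, profile
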