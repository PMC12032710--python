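"""Matching temporal-synergy activation profiles across movement strategies.

Profiles from all strategies of one movement x floor task are clustered with
k-means++ (Euclidean metric on the unit-maximum 101-sample profiles). The
number of clusters grows from one until the first solution that satisfies
both validity constraints: every profile correlates at least 0.9 (Pearson)
with its cluster centroid, and no cluster holds two profiles of the same
strategy. Singleton clusters mark strategy-specific synergies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .timing import find_main_peak, half_max_crossings

CORRELATION_THRESHOLD = 0.9


@dataclass
class ClusterSolution:
    k: int
    strategies: list[str]            # per profile
    profiles: np.ndarray             # (p, 101)
    assignments: np.ndarray          # (p,) cluster index
    centroids: np.ndarray            # (k, 101)
    correlations: np.ndarray         # (p,) Pearson r to own centroid
    valid: bool
    order: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    robustness: float | None = None

    @property
    def singleton_clusters(self) -> list[int]:
        """Clusters holding a single profile: strategy-specific synergies."""
        counts = np.bincount(self.assignments, minlength=self.k)
        return [int(c) for c in np.flatnonzero(counts == 1)]

    def cluster_members(self, c: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.assignments == c)]

    def partition(self) -> frozenset[frozenset[int]]:
        return frozenset(
            frozenset(self.cluster_members(c)) for c in range(self.k)
        )


def _profile_centroid_correlations(
    profiles: np.ndarray, centroids: np.ndarray, assignments: np.ndarray
) -> np.ndarray:
    corr = np.empty(len(profiles))
    counts = np.bincount(assignments, minlength=len(centroids))
    for i, (p, a) in enumerate(zip(profiles, assignments)):
        if counts[a] == 1:
            corr[i] = 1.0  # singleton: centroid equals the profile
            continue
        c = centroids[a]
        ps, cs = p.std(), c.std()
        corr[i] = 0.0 if ps == 0 or cs == 0 else float(np.corrcoef(p, c)[0, 1])
    return corr


def _is_valid(
    assignments: np.ndarray, correlations: np.ndarray, strategies: list[str], k: int
) -> bool:
    if np.any(correlations < CORRELATION_THRESHOLD):
        return False
    for c in range(k):
        members = [strategies[i] for i in np.flatnonzero(assignments == c)]
        if len(members) != len(set(members)):
            return False
    return True


def cluster_profiles(
    profiles: list[tuple[str, np.ndarray]],
    k: int,
    seed: int = 0,
    *,
    restarts: int = 50,
    max_iter: int = 1000,
) -> ClusterSolution:
    """k-means++ clustering of (strategy, profile) pairs; best of ``restarts``
    by within-cluster sum of squares."""
    if not profiles:
        raise ValueError("no profiles to cluster")
    strategies = [s for s, _ in profiles]
    X = np.stack([np.asarray(p, dtype=float) for _, p in profiles])
    if not (1 <= k <= len(X)):
        raise ValueError(f"k must be in [1, {len(X)}], got {k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts, max_iter=max_iter,
        random_state=seed,
    )
    assignments = km.fit_predict(X)
    centroids = km.cluster_centers_
    correlations = _profile_centroid_correlations(X, centroids, assignments)
    valid = _is_valid(assignments, correlations, strategies, k)
    return ClusterSolution(
        k=k, strategies=strategies, profiles=X, assignments=assignments,
        centroids=centroids, correlations=correlations, valid=valid,
    )


def find_min_valid_k(
    profiles: list[tuple[str, np.ndarray]],
    seed: int = 0,
    *,
    restarts: int = 50,
    max_iter: int = 1000,
) -> ClusterSolution:
    """Smallest k whose solution satisfies both matching constraints.

    Always terminates: at k = number of profiles every cluster is a singleton,
    which satisfies both constraints trivially.
    """
    last = None
    for k in range(1, len(profiles) + 1):
        last = cluster_profiles(
            profiles, k, seed=seed, restarts=restarts, max_iter=max_iter
        )
        if last.valid:
            return order_clusters_chronologically(last)
    return order_clusters_chronologically(last)  # pragma: no cover


def order_clusters_chronologically(solution: ClusterSolution) -> ClusterSolution:
    """Sort clusters by centroid main-peak index; ties broken by the earlier
    ascending half-maximum crossing."""
    keys = []
    for c in range(solution.k):
        centroid = solution.centroids[c]
        peak_idx, _ = find_main_peak(np.clip(centroid, 0.0, None))
        left, _right = half_max_crossings(np.clip(centroid, 0.0, None), peak_idx)
        keys.append((peak_idx, left if left is not None else -1.0, c))
    order = np.array([c for _, _, c in sorted(keys)], dtype=int)
    solution.order = order
    return solution


def robustness_check(
    profiles: list[tuple[str, np.ndarray]],
    repeats: int = 10,
    seed: int = 0,
    *,
    restarts: int = 50,
    max_iter: int = 1000,
) -> float:
    """Fraction of repeat pairs whose partitions agree exactly.

    Partitions are compared as sets of profile-index sets, which is invariant
    to cluster labeling. A fraction below 1 is reported with a warning.
    """
    partitions = []
    for r in range(repeats):
        sol = find_min_valid_k(
            profiles, seed=seed + r, restarts=restarts, max_iter=max_iter
        )
        partitions.append(sol.partition())
    pairs = 0
    agree = 0
    for i in range(repeats):
        for j in range(i + 1, repeats):
            pairs += 1
            agree += partitions[i] == partitions[j]
    frac = agree / pairs if pairs else 1.0
    if frac < 1.0:
        warnings.warn(
            f"cluster assignments agree in only {frac:.0%} of repeat pairs"
        )
    return frac
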