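"""Grouping of alternatives and best-in-class benchmarking.

Distances are Euclidean on the normalized, *unweighted* matrix (weights
enter the ranking, not the grouping).  The partition into exactly K groups
comes from one of two routes:

1. DBSCAN over a precomputed distance matrix, with (eps, minPts) chosen by
   exhaustive grid search maximizing the mean silhouette coefficient.  The
   DBSCAN winner is adopted only when it yields exactly K noise-free
   clusters.
2. Otherwise a deterministic two-round merge designed for small samples:
   round one links every point to its nearest neighbor; round two
   repeatedly merges the two groups with the smallest average inter-group
   distance (the mean over all cross pairs) until exactly K groups remain.

Each group's benchmark ("best-in-class") is its member with the highest
overall score.
"""

from __future__ import annotations

import logging
from collections import deque

import numpy as np

from .types import (ClusterResult, DistanceMatrix, GridSearchReport,
                    NormalizedMatrix, PipelineConfig)

logger = logging.getLogger(__name__)

NOISE = -1


class InvalidClusteringError(ValueError):
    """Labeling unusable for a silhouette score (fewer than 2 real clusters)."""


def pairwise_distance_matrix(X: NormalizedMatrix) -> DistanceMatrix:
    """Euclidean distances D_ik = sqrt(sum_j (x_ij - x_kj)^2)."""
    V = np.asarray(X.values, dtype=float)
    diff = V[:, None, :] - V[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=D)


def dbscan_labels(D: DistanceMatrix | np.ndarray, eps: float,
                  minpts: int) -> np.ndarray:
    """Classical DBSCAN on a precomputed distance matrix.

    A point is a core point iff its eps-neighborhood (itself included)
    holds at least ``minpts`` points.  Clusters are grown breadth-first
    from core points in deterministic index order; border points attach to
    the first core that reaches them; unreachable points get label -1
    (noise).  Cluster labels are 0, 1, ... in discovery order.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if minpts < 2:
        raise ValueError("minpts must be at least 2")
    m = Dv.shape[0]
    adjacency = Dv <= eps
    core = adjacency.sum(axis=1) >= minpts
    labels = np.full(m, NOISE, dtype=int)
    cluster = 0
    for i in range(m):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cluster
        queue = deque(np.flatnonzero(adjacency[i]))
        while queue:
            q = int(queue.popleft())
            if labels[q] == NOISE:
                labels[q] = cluster
                if core[q]:
                    queue.extend(np.flatnonzero(adjacency[q]))
        cluster += 1
    return labels


def silhouette_mean(D: DistanceMatrix | np.ndarray,
                    labels: np.ndarray) -> float:
    """Mean silhouette s = (b - a)/max(a, b) over non-noise samples.

    a is the mean distance to same-cluster points, b the smallest mean
    distance to another cluster; singleton clusters score 0.  Raises
    :class:`InvalidClusteringError` when fewer than two clusters (or fewer
    than two non-noise points) are present.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    labels = np.asarray(labels)
    keep = labels != NOISE
    if keep.sum() < 2:
        raise InvalidClusteringError("fewer than 2 non-noise points")
    uniq = np.unique(labels[keep])
    if uniq.size < 2:
        raise InvalidClusteringError("fewer than 2 clusters among non-noise points")
    s_values = []
    for i in np.flatnonzero(keep):
        same = keep & (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            s_values.append(0.0)
            continue
        a = Dv[i, same].sum() / (n_same - 1)
        b = min(Dv[i, keep & (labels == c)].mean()
                for c in uniq if c != labels[i])
        s_values.append((b - a) / max(a, b))
    return float(np.mean(s_values))


def _n_clusters(labels: np.ndarray) -> int:
    return int(np.unique(labels[labels != NOISE]).size)


def grid_search_dbscan(D: DistanceMatrix | np.ndarray,
                       cfg: PipelineConfig) -> GridSearchReport:
    """Exhaustive (eps, minPts) search maximizing the mean silhouette.

    Every combination on the configured lattice is evaluated; combinations
    whose labeling is invalid for a silhouette are skipped.  Ties are broken
    toward smaller minPts, then smaller eps.  If no combination is valid,
    the report carries ``n_valid_combos = 0`` and empty winners, signalling
    the fallback merge.

    The DBSCAN outcome only changes when eps crosses a pairwise distance,
    so results are computed once per (distance interval, minPts) cell and
    shared across all eps values inside the interval; the selection is
    identical to evaluating every combination directly.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    eps_grid = cfg.eps_grid()
    minpts_list = list(cfg.minpts_grid())
    n_total = eps_grid.size * len(minpts_list)

    iu = np.triu_indices_from(Dv, k=1)
    thresholds = np.unique(Dv[iu])
    keys = np.searchsorted(thresholds, eps_grid, side="right")
    unique_keys, first_idx, counts = np.unique(keys, return_index=True,
                                               return_counts=True)

    n_valid = 0
    best = None  # (silhouette, minpts, eps)
    for minpts in minpts_list:
        for key, idx, count in zip(unique_keys, first_idx, counts):
            eps = float(eps_grid[idx])
            labels = dbscan_labels(Dv, eps, minpts)
            try:
                s = silhouette_mean(Dv, labels)
            except InvalidClusteringError:
                continue
            n_valid += int(count)
            if best is None or s > best[0]:
                best = (s, minpts, eps)
    if best is None:
        logger.info("grid search: no valid (eps, minPts) combination "
                    "out of %d", n_total)
        return GridSearchReport(eps_best=None, minpts_best=None,
                                silhouette_best=None, n_valid_combos=0,
                                n_total_combos=n_total)
    s, minpts, eps = best
    logger.info("grid search: %d/%d valid combos; best eps=%g minPts=%d "
                "silhouette=%.4f", n_valid, n_total, eps, minpts, s)
    return GridSearchReport(eps_best=eps, minpts_best=minpts,
                            silhouette_best=s, n_valid_combos=n_valid,
                            n_total_combos=n_total)


def average_intergroup_distance(D: np.ndarray, group_a: list[int],
                                group_b: list[int]) -> float:
    """Mean of all cross-pair distances between two groups."""
    return float(D[np.ix_(group_a, group_b)].mean())


def two_round_merge(D: DistanceMatrix | np.ndarray, k: int) -> np.ndarray:
    """Small-sample agglomeration to exactly ``k`` groups.

    Round one unions every point with its nearest neighbor (ties to the
    smallest index).  If that leaves more than ``k`` groups, round two
    repeatedly merges the pair of groups with the smallest average
    inter-group distance until exactly ``k`` remain.  If round one already
    gives ``k`` or fewer groups, the procedure restarts from singletons and
    runs round-two merging only, which guarantees exactly ``k`` groups.

    Returns integer labels 1..k, groups numbered by smallest member index.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    m = Dv.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..{m}, got {k}")

    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        d = Dv[i].copy()
        d[i] = np.inf
        nn = int(np.argmin(d))  # first minimum = smallest index on ties
        parent[find(i)] = find(nn)

    groups_map: dict[int, list[int]] = {}
    for i in range(m):
        groups_map.setdefault(find(i), []).append(i)
    groups = sorted(groups_map.values(), key=min)

    if len(groups) <= k:
        groups = [[i] for i in range(m)]

    while len(groups) > k:
        best = None  # (distance, a, b)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                dab = average_intergroup_distance(Dv, groups[a], groups[b])
                if best is None or dab < best[0]:
                    best = (dab, a, b)
        _, a, b = best
        merged = sorted(groups[a] + groups[b])
        groups = [g for idx, g in enumerate(groups) if idx not in (a, b)]
        groups.append(merged)
        groups.sort(key=min)

    labels = np.empty(m, dtype=int)
    for gid, members in enumerate(groups, start=1):
        labels[members] = gid
    return labels


def best_in_class(labels: np.ndarray, scores: np.ndarray,
                  alternatives: list[str]) -> dict[int, str]:
    """Per-group benchmark: member with the maximal score, ties to the
    lexicographically smallest alternative id."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    benchmarks: dict[int, str] = {}
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        top = max(scores[members])
        ids = sorted(alternatives[i] for i in members
                     if scores[i] == top)
        benchmarks[int(g)] = ids[0]
    return benchmarks


def cluster_alternatives(X: NormalizedMatrix, scores: np.ndarray,
                         cfg: PipelineConfig) -> ClusterResult:
    """Grid-searched DBSCAN with two-round-merge fallback, plus benchmarks.

    The DBSCAN winner is adopted only when it produces exactly
    ``cfg.target_k`` clusters with no noise; otherwise the two-round merge
    decides the partition.  Final group ids 1..K are ordered by descending
    best member score (group 1 holds the overall top scorer).
    """
    D = pairwise_distance_matrix(X)
    report = grid_search_dbscan(D, cfg)
    labels = None
    source = "fallback_merge"
    if report.n_valid_combos > 0:
        cand = dbscan_labels(D, report.eps_best, report.minpts_best)
        if _n_clusters(cand) == cfg.target_k and np.all(cand != NOISE):
            labels = cand + 1
            source = "dbscan"
    if labels is None:
        labels = two_round_merge(D, cfg.target_k)
    logger.info("clustering source=%s groups=%d", source,
                np.unique(labels).size)

    scores = np.asarray(scores, dtype=float)
    order = sorted(np.unique(labels),
                   key=lambda g: (-scores[labels == g].max(),
                                  min(np.array(X.alternatives)[labels == g])))
    relabel = {int(g): rank for rank, g in enumerate(order, start=1)}
    final = np.array([relabel[int(g)] for g in labels])
    benchmarks = best_in_class(final, scores, X.alternatives)
    return ClusterResult(labels=final, source=source, report=report,
                         benchmarks=benchmarks)
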