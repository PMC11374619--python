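"""Distances, DBSCAN, silhouette, grid search, two-round merge and
benchmark selection against reference implementations and boundary cases."""

import numpy as np
import pytest

from spibench import (PipelineConfig, best_in_class, cluster_alternatives,
                      dbscan_labels, grid_search_dbscan, grouping_agreement,
                      pairwise_distance_matrix, silhouette_mean,
                      two_round_merge)
from spibench.cluster import InvalidClusteringError, average_intergroup_distance
from spibench.published import GROUPS, SCORES
from .conftest import make_normalized


def dist(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))


def same_partition(a, b):
    """Partitions equal up to relabeling; noise (-1) must match exactly."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    keep = a != -1
    return grouping_agreement(a[keep], b[keep]) == pytest.approx(1.0) \
        if keep.sum() > 1 else True


def merge_oracle(D, k):
    """Independent re-implementation of the two-round merge rules using
    explicit frozensets."""
    m = D.shape[0]
    groups = []
    assigned = {}
    pairs = []
    for i in range(m):
        d = D[i].copy()
        d[i] = np.inf
        pairs.append((i, int(np.argmin(d))))
    # connected components of the nearest-neighbor graph
    comp = {i: {i} for i in range(m)}
    for i, j in pairs:
        ci = next(c for c in comp.values() if i in c)
        cj = next(c for c in comp.values() if j in c)
        if ci is not cj:
            ci |= cj
            for member in cj:
                comp[member] = ci
    groups = sorted({frozenset(c) for c in comp.values()}, key=min)
    if len(groups) <= k:
        groups = [frozenset([i]) for i in range(m)]
    while len(groups) > k:
        best = None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                dab = np.mean([D[i, j] for i in groups[a] for j in groups[b]])
                if best is None or dab < best[0]:
                    best = (dab, a, b)
        _, a, b = best
        merged = groups[a] | groups[b]
        groups = [g for t, g in enumerate(groups) if t not in (a, b)]
        groups.append(merged)
        groups.sort(key=min)
    labels = np.empty(m, dtype=int)
    for gid, g in enumerate(groups, start=1):
        for i in g:
            labels[i] = gid
    return labels


# ---------------------------------------------------------------- distances

def test_distance_identical_rows_zero():
    X = make_normalized([[0.2, 0.8], [0.2, 0.8], [1.0, 0.0]])
    D = pairwise_distance_matrix(X).values
    assert D[0, 1] == 0.0


def test_distance_pythagorean():
    X = make_normalized([[0.0, 0.0], [3.0, 4.0]])
    assert pairwise_distance_matrix(X).values[0, 1] == pytest.approx(5.0)


def test_distance_matches_double_loop(rng):
    V = rng.random((6, 4))
    D = pairwise_distance_matrix(make_normalized(V)).values
    for i in range(6):
        for k in range(6):
            expect = np.sqrt(((V[i] - V[k]) ** 2).sum())
            assert D[i, k] == pytest.approx(expect, abs=1e-12)
    np.testing.assert_allclose(D, D.T)
    np.testing.assert_array_equal(np.diag(D), 0.0)


# ------------------------------------------------------------------- dbscan

def test_dbscan_minpts_above_m_all_noise():
    D = dist([[0, 0], [0.1, 0], [0, 0.1]])
    np.testing.assert_array_equal(dbscan_labels(D, 1.0, 5), [-1, -1, -1])


def test_dbscan_all_identical_one_cluster():
    D = np.zeros((4, 4))
    np.testing.assert_array_equal(dbscan_labels(D, 0.5, 4), [0, 0, 0, 0])


def test_dbscan_matches_reference_implementation(rng):
    from sklearn.cluster import DBSCAN
    for _ in range(60):
        pts = rng.random((20, 2))
        D = dist(pts)
        eps = float(rng.uniform(0.05, 0.5))
        mp = int(rng.integers(2, 6))
        mine = dbscan_labels(D, eps, mp)
        ref = DBSCAN(eps=eps, min_samples=mp, metric="precomputed").fit(D)
        assert same_partition(mine, ref.labels_)


def test_dbscan_order_invariant_up_to_relabel(rng):
    pts = rng.random((15, 2))
    D = dist(pts)
    perm = rng.permutation(15)
    a = dbscan_labels(D, 0.3, 3)
    b = dbscan_labels(D[np.ix_(perm, perm)], 0.3, 3)
    assert same_partition(a[perm], b)


# --------------------------------------------------------------- silhouette

def test_silhouette_two_far_pairs_near_one():
    D = dist([0.0, 0.05, 10.0, 10.05])
    s = silhouette_mean(D, np.array([0, 0, 1, 1]))
    assert s > 0.9


def test_silhouette_single_cluster_invalid():
    D = dist([0.0, 1.0, 2.0])
    with pytest.raises(InvalidClusteringError):
        silhouette_mean(D, np.array([0, 0, 0]))


def test_silhouette_integer_toy_hand_value():
    # clusters {0,1} and {2,3,4} on a line at 0, 1, 10, 11, 12
    D = dist([0.0, 1.0, 10.0, 11.0, 12.0])
    labels = np.array([0, 0, 1, 1, 1])
    # hand evaluation of s=(b-a)/max(a,b) per point
    expected = np.mean([
        (11 - 1) / 11,          # point 0: a=1, b=(10+11+12)/3=11
        (10 - 1) / 10,          # point 1: a=1, b=(9+10+11)/3=10
        (9.5 - 1.5) / 9.5,      # point 2: a=1.5, b=(10+9)/2
        (10.5 - 1) / 10.5,      # point 3: a=1,   b=(11+10)/2
        (11.5 - 1.5) / 11.5,    # point 4: a=1.5, b=(12+11)/2
    ])
    assert silhouette_mean(D, labels) == pytest.approx(expected, abs=1e-12)


def test_silhouette_matches_reference(rng):
    from sklearn.metrics import silhouette_samples
    for _ in range(30):
        pts = rng.random((12, 3))
        D = dist(pts)
        labels = rng.integers(0, 3, size=12)
        if np.unique(labels).size < 2:
            continue
        mine = silhouette_mean(D, labels)
        ref = silhouette_samples(D, labels, metric="precomputed").mean()
        assert mine == pytest.approx(ref, abs=1e-9)


# -------------------------------------------------------------- grid search

def grid_cfg(start, stop, step, mp_min=2, mp_max=4):
    return PipelineConfig(eps_start=start, eps_stop=stop, eps_step=step,
                          minpts_min=mp_min, minpts_max=mp_max)


def test_grid_single_valid_combo_wins():
    D = dist([0.0, 0.1, 5.0, 5.1])
    cfg = grid_cfg(0.5, 0.5, 1.0, 2, 2)  # a single combination
    rep = grid_search_dbscan(D, cfg)
    assert rep.n_total_combos == 1
    assert rep.n_valid_combos == 1
    assert rep.eps_best == pytest.approx(0.5)
    assert rep.minpts_best == 2


def test_grid_tie_prefers_smaller_minpts_then_eps():
    # two tight pairs: every eps in [0.2, 4.9] and minpts=2 gives the same
    # perfect 2-cluster partition, so the silhouette ties across the grid
    D = dist([0.0, 0.1, 5.0, 5.1])
    rep = grid_search_dbscan(D, grid_cfg(0.3, 1.5, 0.3, 2, 3))
    assert rep.minpts_best == 2
    assert rep.eps_best == pytest.approx(0.3)


def test_grid_winner_matches_exhaustive_oracle(rng):
    centers = np.array([[0, 0], [4, 0], [0, 4]])
    pts = np.vstack([c + rng.normal(0, 0.3, size=(4, 2)) for c in centers])
    D = dist(pts)
    cfg = grid_cfg(0.2, 2.0, 0.2, 2, 4)  # 10 eps x 3 minpts
    rep = grid_search_dbscan(D, cfg)
    best = None
    n_valid = 0
    for mp in cfg.minpts_grid():
        for eps in cfg.eps_grid():
            labels = dbscan_labels(D, float(eps), mp)
            try:
                s = silhouette_mean(D, labels)
            except InvalidClusteringError:
                continue
            n_valid += 1
            if best is None or s > best[0]:
                best = (s, mp, float(eps))
    assert rep.n_valid_combos == n_valid
    assert rep.silhouette_best == pytest.approx(best[0], abs=1e-12)
    assert (rep.minpts_best, rep.eps_best) == (best[1], pytest.approx(best[2]))


def test_grid_no_valid_combo_reported_not_raised():
    D = dist([0.0, 1.0, 2.0, 3.0])
    rep = grid_search_dbscan(D, grid_cfg(1e-6, 1e-4, 1e-6))
    assert rep.n_valid_combos == 0
    assert rep.eps_best is None


# ---------------------------------------------------------- two-round merge

def test_merge_separated_blobs():
    D = dist([0.0, 0.1, 5.0, 5.1, 10.0])
    labels = two_round_merge(D, 3)
    assert labels.tolist() == [1, 1, 2, 2, 3]


def test_average_intergroup_distance_mean_of_constants():
    D = np.full((6, 6), 2.0)
    np.fill_diagonal(D, 0.0)
    assert average_intergroup_distance(D, [0, 1, 2], [3, 4, 5]) == 2.0


def test_merge_matches_independent_reimplementation(rng):
    for _ in range(20):
        pts = rng.random((9, 2))
        D = dist(pts)
        for k in (2, 3, 4):
            np.testing.assert_array_equal(two_round_merge(D, k),
                                          merge_oracle(D, k))


def test_merge_boundary_identities(rng):
    D = dist(rng.random((6, 2)))
    np.testing.assert_array_equal(two_round_merge(D, 6),
                                  np.arange(1, 7))
    np.testing.assert_array_equal(two_round_merge(D, 1), np.ones(6, int))
    with pytest.raises(ValueError):
        two_round_merge(D, 7)


# ------------------------------------------------------ cluster_alternatives

def blob_matrix(rng, centers, per=4, sd=0.05):
    pts = np.vstack([c + rng.normal(0, sd, size=(per, len(c)))
                     for c in centers])
    return make_normalized(np.clip(pts, 0, 1))


def test_cluster_alternatives_recovers_blobs(rng):
    X = blob_matrix(rng, np.array([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]]))
    scores = -np.arange(12, dtype=float)  # descending quality with index
    cfg = PipelineConfig(eps_start=0.05, eps_stop=1.0, eps_step=0.05,
                         target_k=3)
    result = cluster_alternatives(X, scores, cfg)
    planted = np.repeat([1, 2, 3], 4)
    assert grouping_agreement(result.labels, planted) == pytest.approx(1.0)
    assert np.unique(result.labels).size == 3
    # group 1 must hold the top scorer and every point is labeled
    assert result.labels[0] == 1
    assert result.benchmarks[1] == "a1"


def test_benchmark_is_group_argmax(rng):
    X = blob_matrix(rng, np.array([[0.2, 0.2], [0.8, 0.8]]), per=3)
    scores = np.array([5.0, 1.0, 2.0, 9.0, 8.0, 7.0])
    cfg = PipelineConfig(eps_start=0.05, eps_stop=1.0, eps_step=0.05,
                         target_k=2)
    result = cluster_alternatives(X, scores, cfg)
    for g, bench in result.benchmarks.items():
        members = [a for a, lab in zip(X.alternatives, result.labels)
                   if lab == g]
        best = max(members,
                   key=lambda a: scores[X.alternatives.index(a)])
        assert bench == best


def test_published_2013_group_one_benchmark():
    """Given the published 2013 group-I membership and printed scores, the
    best-in-class rule selects BN (largest printed score, 5.648)."""
    members = GROUPS[2013]["I"]
    labels = np.ones(len(members), dtype=int)
    scores = np.array([SCORES[2013][c] for c in members])
    assert best_in_class(labels, scores, members) == {1: "BN"}
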