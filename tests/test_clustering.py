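"""k-medoids, triviality, similarity metrics, and the robustness procedure."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from icupheno import (
    Clustering,
    cluster_kmedoids,
    clustering_similarity,
    find_robust_clusterings,
    is_trivial,
    robustness_assess,
)
from icupheno.cohort import SizingError


def _blobs(n_per, centers, scale=1.0, seed=0):
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for i, c in enumerate(centers):
        parts.append(rng.normal(loc=c, scale=scale, size=(n_per, len(c))))
        labels.extend([i] * n_per)
    return np.concatenate(parts), np.asarray(labels)


# -- k-medoids --------------------------------------------------------------


def test_k_one_single_label():
    x, _ = _blobs(10, [(0.0, 0.0)])
    c = cluster_kmedoids(x, k=1, seed=0)
    assert set(c.labels) == {0}


def test_separated_blobs_recovered():
    x, truth = _blobs(50, [(0.0, 0.0), (10.0, 10.0)], scale=1.0, seed=1)
    c = cluster_kmedoids(x, k=2, seed=0)
    assert adjusted_rand_score(truth, c.labels) == 1.0


def test_medoids_are_data_points():
    x, _ = _blobs(30, [(0.0, 0.0), (5.0, 5.0)], seed=2)
    c = cluster_kmedoids(x, k=2, seed=0)
    assert all(0 <= i < len(x) for i in c.medoid_indices)
    for m in c.medoid_indices:
        assert np.any(np.all(x == x[m], axis=1))


def test_k_larger_than_n_rejected():
    x, _ = _blobs(3, [(0.0,)])
    with pytest.raises(SizingError):
        cluster_kmedoids(x, k=5, seed=0)


def test_seeded_determinism():
    x, _ = _blobs(40, [(0, 0), (4, 4), (8, 0)], seed=3)
    a = cluster_kmedoids(x, k=3, seed=7)
    b = cluster_kmedoids(x, k=3, seed=7)
    assert np.array_equal(a.labels, b.labels)


# -- triviality -------------------------------------------------------------


def _clustering_from_labels(labels, k):
    return Clustering(np.asarray(labels), k=k, medoid_indices=np.empty(0, int), seed=0)


def test_single_cluster_is_trivial():
    assert is_trivial(_clustering_from_labels([0] * 20, k=1))
    assert is_trivial(_clustering_from_labels([1] * 20, k=2))  # one non-empty


def test_ninety_percent_boundary_is_strict():
    # 100 points: exactly 90 in one cluster -> NOT trivial; 91 -> trivial
    at_boundary = _clustering_from_labels([0] * 90 + [1] * 10, k=2)
    over = _clustering_from_labels([0] * 91 + [1] * 9, k=2)
    assert not is_trivial(at_boundary)
    assert is_trivial(over)


def test_balanced_clustering_not_trivial():
    assert not is_trivial(_clustering_from_labels([0] * 50 + [1] * 50, k=2))


# -- similarity metrics -----------------------------------------------------


def _pair_sets(labels):
    n = len(labels)
    return {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if labels[i] == labels[j]
    }


def _brute_rand(a, b):
    n = len(a)
    pa, pb = _pair_sets(a), _pair_sets(b)
    total = n * (n - 1) // 2
    agree = len(pa & pb) + (total - len(pa | pb))
    return agree / total


def _brute_jaccard(a, b):
    pa, pb = _pair_sets(a), _pair_sets(b)
    union = pa | pb
    if not union:
        return 1.0
    return len(pa & pb) / len(union)


def test_label_literal_permutation_is_identity():
    a = np.array([0, 0, 1, 1])
    b = np.array([1, 1, 0, 0])
    for metric in ("nmi", "rand", "jaccard"):
        assert clustering_similarity(a, b, metric) == pytest.approx(
            clustering_similarity(a, a, metric)
        )


def test_identical_labelings_maximal():
    a = np.array([0, 1, 2, 0, 1, 2])
    assert clustering_similarity(a, a, "rand") == 1.0
    assert clustering_similarity(a, a, "jaccard") == 1.0
    assert clustering_similarity(a, a, "nmi") == pytest.approx(1.0)


def test_jaccard_disjoint_pair_sets():
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 0, 1])
    # co-assigned pairs {01,23} vs {02,13}: disjoint -> Jaccard 0
    assert clustering_similarity(a, b, "jaccard") == 0.0


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=30),
    st.data(),
)
def test_metrics_match_brute_force_pair_counting(a, data):
    b = data.draw(st.lists(st.integers(0, 3), min_size=len(a), max_size=len(a)))
    a, b = np.asarray(a), np.asarray(b)
    assert clustering_similarity(a, b, "rand") == pytest.approx(_brute_rand(a, b))
    assert clustering_similarity(a, b, "jaccard") == pytest.approx(_brute_jaccard(a, b))
    # symmetry and permutation invariance for all three metrics
    perm = {v: i for i, v in enumerate(dict.fromkeys(b.tolist()))}
    b_perm = np.asarray([10 + perm[v] for v in b.tolist()])
    for metric in ("nmi", "rand", "jaccard"):
        s_ab = clustering_similarity(a, b, metric)
        assert clustering_similarity(b, a, metric) == pytest.approx(s_ab)
        assert clustering_similarity(a, b_perm, metric) == pytest.approx(s_ab)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        clustering_similarity(np.array([0, 1]), np.array([0, 1, 2]), "rand")


# -- robustness -------------------------------------------------------------


def test_well_separated_blobs_are_robust():
    x, _ = _blobs(100, [(0.0, 0.0), (10.0, 10.0)], scale=1.0, seed=4)
    full = cluster_kmedoids(x, k=2, seed=0)
    record = robustness_assess(x, full, seed=0)
    assert record.robust
    for h in ("rand", "jaccard"):
        assert record.rob[h] == pytest.approx(1.0)
        assert record.rob[h] > record.thresh[h]


def test_exact_bootstrap_copies_give_rob_one(monkeypatch):
    """If every bootstrap reproduces the full labels exactly, the 10th
    percentile of similarities hits each metric's maximum."""
    x, truth = _blobs(40, [(0.0, 0.0), (8.0, 8.0)], seed=5)
    full = cluster_kmedoids(x, k=2, seed=0)

    import icupheno.clustering as mod

    def echo_full_labels(features, k, seed=0, max_iter=100):
        # identify the subsample rows in x and echo the full labels for them
        idx = [int(np.flatnonzero(np.all(x == row, axis=1))[0]) for row in features]
        return Clustering(full.labels[idx], k=k,
                          medoid_indices=np.empty(0, int), seed=seed)

    monkeypatch.setattr(mod, "cluster_kmedoids", echo_full_labels)
    record = mod.robustness_assess(x, full, seed=3)
    assert record.rob["rand"] == 1.0
    assert record.rob["jaccard"] == 1.0
    assert record.robust


def test_thresholds_depend_on_cluster_size_profile():
    x = np.random.default_rng(0).normal(size=(100, 3))
    balanced = _clustering_from_labels([0] * 50 + [1] * 50, k=2)
    skewed = _clustering_from_labels([0] * 85 + [1] * 15, k=2)
    rec_a = robustness_assess(x, balanced, seed=1)
    rec_b = robustness_assess(x, skewed, seed=1)
    assert any(rec_a.thresh[h] != rec_b.thresh[h] for h in rec_a.thresh)


def test_subsample_too_small_rejected():
    x = np.random.default_rng(0).normal(size=(10, 2))
    full = cluster_kmedoids(x, k=2, seed=0)
    with pytest.raises(SizingError):
        robustness_assess(x, full, sample_frac=0.1, seed=0)


def test_bootstrap_without_replacement():
    rng = np.random.default_rng(0)
    idx = rng.choice(200, size=140, replace=False)
    assert len(np.unique(idx)) == 140  # documented sampling mode of the draw


def test_find_robust_clusterings_recovers_true_k():
    x, _ = _blobs(60, [(0, 0), (10, 10), (0, 10)], scale=1.0, seed=6)
    results = find_robust_clusterings(x, k_values=[2, 3], seed=0)
    assert any(c.k == 3 for c, _ in results)
    ks = [c.k for c, _ in results]
    assert ks == sorted(ks)


def test_find_robust_clusterings_k1_all_trivial():
    x, _ = _blobs(30, [(0, 0), (5, 5)], seed=7)
    assert find_robust_clusterings(x, k_values=[1], seed=0) == []
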