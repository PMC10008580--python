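"""k-medoids clustering with a bootstrap robustness criterion.

Clustering runs on the flat feature space (one embedding per admission) with
the k-medoids algorithm under k-medoids++ seeding, which is more robust to
outliers than k-means.  Because repeated clustering of the same data can
disagree, every candidate clustering is screened:

* **Triviality** — a clustering is trivial if it effectively has one cluster,
  i.e. only a single non-empty cluster or a largest cluster holding strictly
  more than 90% of the points.
* **Robustness** — the same clustering procedure is re-run on ``n_b`` (default
  10) bootstrap subsamples of 70% of the points drawn without replacement.
  For each similarity metric h (normalized mutual information, Rand index,
  pairwise Jaccard index) the robustness lower bound ``rob_h`` is the 10th
  percentile of the similarities between the full-data labels (restricted to
  the subsample) and the bootstrap labels.  The threshold ``thresh_h`` is the
  90th percentile of similarities between the full labeling and uniform
  shuffles of itself, recomputed per clustering because it depends on the
  cluster-size profile.  A clustering is robust iff ``rob_h > thresh_h``
  (strict) for all three metrics.

All similarity metrics operate on co-assignment structure only and are
invariant to permutations of the label literals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import normalized_mutual_info_score, rand_score
from sklearn.metrics.cluster import pair_confusion_matrix

from .autoencoder import FeatureMatrix
from .cohort import SizingError

SIMILARITY_METRICS = ("nmi", "rand", "jaccard")


@dataclass
class Clustering:
    labels: np.ndarray  # (N,) ints in [0, k)
    k: int
    medoid_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class RobustnessRecord:
    n_b: int
    sample_frac: float
    similarities: dict[str, np.ndarray] = field(default_factory=dict)
    rob: dict[str, float] = field(default_factory=dict)
    thresh: dict[str, float] = field(default_factory=dict)
    robust: bool = False


def _kmedoidspp_init(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids++ seeding: spread initial medoids via squared-distance sampling."""
    n = dist.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(dist[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total <= 0:  # duplicate points; fall back to uniform over the rest
            candidates = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(candidates)))
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    return np.asarray(medoids)


def cluster_kmedoids(features: FeatureMatrix | np.ndarray, k: int, seed: int = 0,
                     max_iter: int = 100) -> Clustering:
    """Seeded k-medoids (alternating assignment / medoid update) on Euclidean
    distances, initialized with k-medoids++."""
    x = features.embeddings if isinstance(features, FeatureMatrix) else np.asarray(features)
    n = x.shape[0]
    if k < 1:
        raise SizingError("k must be >= 1")
    if k > n:
        raise SizingError(f"k={k} exceeds the number of points n={n}")

    sq = (x * x).sum(axis=1)
    dist = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0))

    rng = np.random.default_rng(seed)
    medoids = _kmedoidspp_init(dist, k, rng)
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return Clustering(labels=labels, k=k, medoid_indices=medoids, seed=seed)


def is_trivial(clustering: Clustering, max_cluster_frac: float = 0.9) -> bool:
    """True iff the clustering has one non-empty cluster or its largest cluster
    holds strictly more than ``max_cluster_frac`` of the points."""
    sizes = clustering.cluster_sizes()
    nonempty = sizes[sizes > 0]
    if nonempty.size <= 1:
        return True
    return bool(nonempty.max() > max_cluster_frac * sizes.sum())


def clustering_similarity(labels_a: np.ndarray, labels_b: np.ndarray,
                          metric: str) -> float:
    """Label-permutation-invariant similarity between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("labelings must contain at least 2 points")
    if metric == "nmi":
        if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
            return 1.0  # both degenerate single-cluster labelings agree fully
        return float(normalized_mutual_info_score(a, b))
    if metric == "rand":
        return float(rand_score(a, b))
    if metric == "jaccard":
        c = pair_confusion_matrix(a, b)
        tp, fp, fn = c[1, 1], c[0, 1], c[1, 0]
        denom = tp + fp + fn
        if denom == 0:  # no co-assigned pairs on either side
            return 1.0
        return float(tp / denom)
    raise ValueError(f"unknown similarity metric {metric!r}")


def robustness_assess(features: FeatureMatrix | np.ndarray,
                      full_clustering: Clustering, n_b: int = 10,
                      sample_frac: float = 0.7, seed: int = 0,
                      metrics: tuple[str, ...] = SIMILARITY_METRICS,
                      ) -> RobustnessRecord:
    """Bootstrap robustness check of one clustering against its shuffles."""
    x = features.embeddings if isinstance(features, FeatureMatrix) else np.asarray(features)
    n = x.shape[0]
    m = int(np.floor(sample_frac * n))
    if m < full_clustering.k:
        raise SizingError(
            f"subsample size {m} smaller than k={full_clustering.k}"
        )

    rng = np.random.default_rng(seed)
    record = RobustnessRecord(n_b=n_b, sample_frac=sample_frac)
    sims: dict[str, list[float]] = {h: [] for h in metrics}
    for j in range(n_b):
        idx = rng.choice(n, size=m, replace=False)
        sub = cluster_kmedoids(x[idx], full_clustering.k,
                               seed=int(rng.integers(2**31)))
        ref = full_clustering.labels[idx]
        for h in metrics:
            sims[h].append(clustering_similarity(ref, sub.labels, h))

    shuffle_sims: dict[str, list[float]] = {h: [] for h in metrics}
    for j in range(n_b):
        shuffled = rng.permutation(full_clustering.labels)
        for h in metrics:
            shuffle_sims[h].append(
                clustering_similarity(full_clustering.labels, shuffled, h)
            )

    robust = True
    for h in metrics:
        record.similarities[h] = np.asarray(sims[h])
        record.rob[h] = float(np.percentile(sims[h], 10))
        record.thresh[h] = float(np.percentile(shuffle_sims[h], 90))
        robust &= record.rob[h] > record.thresh[h]
    record.robust = robust
    return record


def find_robust_clusterings(
    features: FeatureMatrix | np.ndarray,
    k_values: list[int],
    seeds_per_k: int = 1,
    n_b: int = 10,
    sample_frac: float = 0.7,
    seed: int = 0,
) -> list[tuple[Clustering, RobustnessRecord]]:
    """Candidate clusterings over k_values x seeds, minus trivial or fragile ones.

    Multiple surviving clusterings are all returned (they complement rather
    than compete with each other); the list is sorted by (k, seed).
    """
    if not k_values:
        raise ValueError("k_values must be non-empty")
    results: list[tuple[Clustering, RobustnessRecord]] = []
    for k in sorted(k_values):
        for s in range(seeds_per_k):
            cand_seed = seed * 10007 + k * 101 + s
            cand = cluster_kmedoids(features, k, seed=cand_seed)
            if is_trivial(cand):
                continue
            record = robustness_assess(
                features, cand, n_b=n_b, sample_frac=sample_frac,
                seed=cand_seed + 1,
            )
            if record.robust:
                results.append((cand, record))
    return results
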