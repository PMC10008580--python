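"""Cluster characterization by frequent diagnosis/procedure itemsets.

Maximal frequent itemsets of ICD-9-style codes are mined once on the whole
population (a set of codes is *frequent* when at least ``min_support`` of the
admissions exhibit all of its codes, and *maximal* when no frequent proper
superset exists).  Each itemset is then tested in every cluster against the
cluster's complement with a two-sided Fisher exact test on the 2x2 table
(with/without itemset x cluster/complement).  Direction is assigned from the
support comparison: positively enriched when the itemset is more frequent in
the cluster than in the complement, negatively when less.  The relative
enrichment is ``s_c / s_comp - 1`` expressed as a percentage.  Significance is
Bonferroni-controlled per clustering: alpha (default 0.01) divided by
``n_t = n_is * n_c``, the number of distinct itemsets times the number of
clusters.

Diagnoses and procedures run through the same machinery separately.  A small
built-in table maps ICD-9 codes to top-level chapters (e.g. 460-519 ->
respiratory) for category-distribution summaries, counting every diagnosis
occurrence without per-admission de-duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .cohort import Admission, SizingError
from .clustering import Clustering

logger = logging.getLogger("icupheno")


@dataclass(frozen=True)
class Itemset:
    codes: frozenset[str]
    support_population: float

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("itemset must be non-empty")
        if not 0.0 <= self.support_population <= 1.0:
            raise ValueError("support must lie in [0, 1]")

    def sorted_codes(self) -> tuple[str, ...]:
        return tuple(sorted(self.codes))


@dataclass
class EnrichmentResult:
    itemset: Itemset
    support_cluster: float
    support_complement: float
    relative_enrichment_pct: float  # s_c / s_comp - 1, in percent; nan if undefined
    p_value: float
    direction: str  # "positive" | "negative" | "none"
    significant: bool = False


@dataclass
class EnrichmentConfig:
    alpha: float = 0.01
    min_support: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError("min_support must lie in (0, 1]")


# ---------------------------------------------------------------------------
# maximal frequent itemset mining
# ---------------------------------------------------------------------------


def mine_maximal_itemsets(transactions: list[set[str]],
                          min_support: float) -> list[Itemset]:
    """All maximal frequent itemsets, via a depth-first tidset search.

    Ordering is deterministic: descending support, then lexicographic codes.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must lie in (0, 1]")
    n = len(transactions)
    if n == 0:
        return []
    min_count = min_support * n

    tidsets: dict[str, frozenset[int]] = {}
    for tid, items in enumerate(transactions):
        for item in items:
            tidsets.setdefault(item, set()).add(tid)  # type: ignore[arg-type]
    items = sorted(i for i, t in tidsets.items() if len(t) >= min_count)
    tid = {i: frozenset(tidsets[i]) for i in items}

    frequent: dict[frozenset[str], int] = {}

    def dfs(prefix: tuple[str, ...], prefix_tids: frozenset[int],
            candidates: list[str]) -> None:
        for pos, item in enumerate(candidates):
            new_tids = prefix_tids & tid[item] if prefix else tid[item]
            if len(new_tids) >= min_count:
                new_prefix = prefix + (item,)
                frequent[frozenset(new_prefix)] = len(new_tids)
                dfs(new_prefix, new_tids, candidates[pos + 1 :])

    dfs((), frozenset(range(n)), items)

    # maximality: keep itemsets with no frequent proper superset
    by_size = sorted(frequent, key=len, reverse=True)
    maximal: list[frozenset[str]] = []
    for s in by_size:
        if not any(s < kept for kept in maximal):
            maximal.append(s)

    out = [Itemset(codes=s, support_population=frequent[s] / n) for s in maximal]
    out.sort(key=lambda it: (-it.support_population, it.sorted_codes()))
    return out


def itemset_support(itemset: Itemset | frozenset[str],
                    admissions: list[set[str]]) -> float:
    """Fraction of admissions containing every code of the itemset."""
    if not admissions:
        raise SizingError("support over an empty admission list is undefined")
    codes = itemset.codes if isinstance(itemset, Itemset) else itemset
    hits = sum(1 for t in admissions if codes <= t)
    return hits / len(admissions)


# ---------------------------------------------------------------------------
# exact-test enrichment
# ---------------------------------------------------------------------------


def relative_enrichment_pct(support_cluster: float, support_complement: float) -> float:
    """``s_c / s_comp - 1`` in percent; NaN when the complement support is 0."""
    if support_complement == 0.0:
        return float("nan")
    return (support_cluster / support_complement - 1.0) * 100.0


def fisher_enrichment(itemset: Itemset | frozenset[str],
                      cluster_admissions: list[set[str]],
                      complement_admissions: list[set[str]]) -> EnrichmentResult:
    """Two-sided Fisher exact test of an itemset in cluster vs complement."""
    if not cluster_admissions or not complement_admissions:
        raise ValueError("both the cluster and its complement must be non-empty")
    codes = itemset.codes if isinstance(itemset, Itemset) else frozenset(itemset)
    a = sum(1 for t in cluster_admissions if codes <= t)
    b = sum(1 for t in complement_admissions if codes <= t)
    n_c = len(cluster_admissions)
    n_comp = len(complement_admissions)
    table = np.array([[a, b], [n_c - a, n_comp - b]])
    _, p = fisher_exact(table, alternative="two-sided")

    s_c = a / n_c
    s_comp = b / n_comp
    if s_c > s_comp:
        direction = "positive"
    elif s_c < s_comp:
        direction = "negative"
    else:
        direction = "none"
    if s_comp == 0.0 and s_c > 0.0:
        logger.warning(
            "itemset %s absent from the complement; relative enrichment undefined",
            sorted(codes),
        )
    pop_support = (a + b) / (n_c + n_comp)
    iset = itemset if isinstance(itemset, Itemset) else Itemset(codes, pop_support)
    return EnrichmentResult(
        itemset=iset,
        support_cluster=s_c,
        support_complement=s_comp,
        relative_enrichment_pct=relative_enrichment_pct(s_c, s_comp),
        p_value=float(p),
        direction=direction,
    )


def bonferroni_threshold(alpha: float, n_itemsets: int, n_clusters: int) -> float:
    """Per-clustering corrected alpha: ``alpha / (n_is * n_c)``."""
    if n_itemsets < 1 or n_clusters < 1:
        raise SizingError("Bonferroni threshold undefined without any tests")
    return alpha / (n_itemsets * n_clusters)


@dataclass
class ClusterEnrichment:
    cluster: int
    n_admissions: int
    enriched: list[EnrichmentResult] = field(default_factory=list)
    prevalent: list[EnrichmentResult] = field(default_factory=list)


def enrich_clustering(clustering: Clustering, admissions: list[Admission],
                      code_kind: str = "diagnosis",
                      cfg: EnrichmentConfig | None = None,
                      ) -> dict[int, ClusterEnrichment]:
    """Mine itemsets on the population, test each in every cluster vs complement.

    ``admissions`` must be aligned with ``clustering.labels``.  Per cluster,
    ``enriched`` is sorted by absolute relative enrichment descending and
    ``prevalent`` by cluster support descending.
    """
    cfg = cfg or EnrichmentConfig()
    if len(admissions) != clustering.labels.size:
        raise ValueError("labels are not aligned to the admission list")
    transactions = [a.code_set(code_kind) for a in admissions]
    itemsets = mine_maximal_itemsets(transactions, cfg.min_support)
    if not itemsets:
        return {}

    n_clusters = int(len(np.unique(clustering.labels)))
    corrected = bonferroni_threshold(cfg.alpha, len(itemsets), n_clusters)

    out: dict[int, ClusterEnrichment] = {}
    for c in sorted(np.unique(clustering.labels)):
        in_cluster = [t for t, lab in zip(transactions, clustering.labels) if lab == c]
        complement = [t for t, lab in zip(transactions, clustering.labels) if lab != c]
        if not in_cluster:
            logger.warning("cluster %d has no admissions; skipped", c)
            continue
        results = []
        for iset in itemsets:
            res = fisher_enrichment(iset, in_cluster, complement)
            res.significant = res.p_value <= corrected
            results.append(res)
        enriched = sorted(
            (r for r in results if r.direction != "none"),
            key=lambda r: (-(abs(r.relative_enrichment_pct)
                             if np.isfinite(r.relative_enrichment_pct) else np.inf),
                           r.itemset.sorted_codes()),
        )
        prevalent = sorted(
            results, key=lambda r: (-r.support_cluster, r.itemset.sorted_codes())
        )
        out[int(c)] = ClusterEnrichment(
            cluster=int(c), n_admissions=len(in_cluster),
            enriched=enriched, prevalent=prevalent,
        )
    return out


# ---------------------------------------------------------------------------
# ICD-9 top-level chapters
# ---------------------------------------------------------------------------

ICD9_CHAPTERS: tuple[tuple[int, int, str], ...] = (
    (1, 139, "Infectious and parasitic diseases"),
    (140, 239, "Neoplasms"),
    (240, 279, "Endocrine, nutritional, metabolic, immunity"),
    (280, 289, "Blood and blood-forming organs"),
    (290, 319, "Mental disorders"),
    (320, 389, "Nervous system and sense organs"),
    (390, 459, "Circulatory system"),
    (460, 519, "Respiratory system"),
    (520, 579, "Digestive system"),
    (580, 629, "Genitourinary system"),
    (630, 679, "Pregnancy, childbirth, puerperium"),
    (680, 709, "Skin and subcutaneous tissue"),
    (710, 739, "Musculoskeletal system and connective tissue"),
    (740, 759, "Congenital anomalies"),
    (760, 779, "Perinatal conditions"),
    (780, 799, "Symptoms, signs, ill-defined conditions"),
    (800, 999, "Injury and poisoning"),
)
V_CHAPTER = "Supplementary factors (V codes)"
E_CHAPTER = "External causes (E codes)"
UNKNOWN_CHAPTER = "unknown"


def icd9_chapter(code: str) -> str:
    """Top-level ICD-9 chapter of a diagnosis code, or 'unknown'."""
    code = code.strip().upper()
    if code.startswith("V"):
        return V_CHAPTER
    if code.startswith("E"):
        return E_CHAPTER
    major = code.split(".", 1)[0]
    try:
        value = int(major)
    except ValueError:
        return UNKNOWN_CHAPTER
    for lo, hi, name in ICD9_CHAPTERS:
        if lo <= value <= hi:
            return name
    return UNKNOWN_CHAPTER


def icd_category_counts(admissions: list[Admission]) -> dict[str, int]:
    """Diagnosis occurrences per ICD-9 chapter, counting every occurrence.

    No per-admission de-duplication: an admission with three respiratory codes
    contributes three to the respiratory chapter.  The returned mapping covers
    every chapter (zero counts included) so distributions are comparable; it
    can be normalized to fractions for plotting.
    """
    counts = {name: 0 for _, _, name in ICD9_CHAPTERS}
    counts[V_CHAPTER] = 0
    counts[E_CHAPTER] = 0
    counts[UNKNOWN_CHAPTER] = 0
    for a in admissions:
        for entry in a.codes:
            if entry.kind != "diagnosis":
                continue
            chapter = icd9_chapter(entry.code)
            if chapter == UNKNOWN_CHAPTER:
                logger.warning("unparseable ICD-9 code %r counted as unknown", entry.code)
            counts[chapter] += 1
    return counts
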