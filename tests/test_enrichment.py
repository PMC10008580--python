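"""Itemset mining, Fisher enrichment, Bonferroni control, ICD chapters."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icupheno import (
    Clustering,
    EnrichmentConfig,
    Itemset,
    bonferroni_threshold,
    enrich_clustering,
    fisher_enrichment,
    generate_cohort,
    icd9_chapter,
    icd_category_counts,
    itemset_support,
    mine_maximal_itemsets,
    relative_enrichment_pct,
    truth_labels,
)
from icupheno.cohort import Admission, CodeEntry, Observation, SizingError
from icupheno.synthetic import SimulationConfig


# -- brute-force oracles ----------------------------------------------------


def brute_force_maximal(transactions, min_support):
    """Enumerate every subset of observed codes; keep frequent, then maximal."""
    n = len(transactions)
    universe = sorted(set().union(*transactions)) if transactions else []
    frequent = []
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count >= min_support * n:
                frequent.append((s, count))
    freq_sets = {s for s, _ in frequent}
    return {
        s: c / n
        for s, c in frequent
        if not any(s < other for other in freq_sets)
    }


def hypergeom_two_sided_p(a, b, c, d):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(k):
        return comb(r1, k) * comb(n - r1, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


# -- mining -----------------------------------------------------------------


def test_non_maximal_subsets_suppressed():
    transactions = [{"A", "B"}, {"A", "B"}, {"A"}]
    out = mine_maximal_itemsets(transactions, min_support=2 / 3)
    assert {it.codes for it in out} == {frozenset({"A", "B"})}


def test_identical_transactions_full_support():
    out = mine_maximal_itemsets([{"X", "Y"}] * 4, min_support=1.0)
    assert [it.codes for it in out] == [frozenset({"X", "Y"})]
    assert out[0].support_population == 1.0


def test_empty_transactions_empty_result():
    assert mine_maximal_itemsets([], 0.5) == []


@settings(derandomize=True, max_examples=40)
@given(st.data())
def test_miner_matches_brute_force(data):
    rng_seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(rng_seed)
    n_codes = int(rng.integers(2, 10))
    n_trans = int(rng.integers(1, 50))
    universe = [f"c{i}" for i in range(n_codes)]
    transactions = [
        {c for c in universe if rng.random() < 0.4} for _ in range(n_trans)
    ]
    min_support = float(rng.uniform(0.1, 0.9))
    got = {it.codes: it.support_population
           for it in mine_maximal_itemsets(transactions, min_support)}
    want = brute_force_maximal(transactions, min_support)
    assert got == want


def test_support_is_anti_monotone():
    rng = np.random.default_rng(1)
    transactions = [{f"c{i}" for i in range(6) if rng.random() < 0.5}
                    for _ in range(40)]
    for _ in range(20):
        small = frozenset(f"c{i}" for i in rng.choice(6, 2, replace=False))
        big = small | {f"c{int(rng.integers(6))}"}
        assert itemset_support(small, transactions) >= itemset_support(big, transactions)


def test_itemset_support_values():
    transactions = [{"A"}, {"B"}, {"A", "B"}]
    assert itemset_support(frozenset({"A"}), transactions) == pytest.approx(2 / 3)
    assert itemset_support(frozenset({"A", "B"}), transactions) == pytest.approx(1 / 3)
    assert itemset_support(frozenset({"Z"}), transactions) == 0.0
    with pytest.raises(SizingError):
        itemset_support(frozenset({"A"}), [])


# -- Fisher enrichment ------------------------------------------------------


def _groups_from_counts(a, b, c, d, code="X"):
    cluster = [{code}] * a + [set()] * c
    complement = [{code}] * b + [set()] * d
    return cluster, complement


def test_equal_proportions_not_enriched():
    cluster, complement = _groups_from_counts(5, 5, 5, 5)
    res = fisher_enrichment(frozenset({"X"}), cluster, complement)
    assert res.p_value == pytest.approx(1.0)
    assert res.direction == "none"


def test_perfect_separation_p_value():
    cluster, complement = _groups_from_counts(10, 0, 0, 10)
    res = fisher_enrichment(frozenset({"X"}), cluster, complement)
    assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)
    assert res.direction == "positive"
    assert np.isnan(res.relative_enrichment_pct)  # complement support is zero


def test_fisher_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 12, size=4)
        if (a + c) == 0 or (b + d) == 0:
            continue
        cluster, complement = _groups_from_counts(int(a), int(b), int(c), int(d))
        res = fisher_enrichment(frozenset({"X"}), cluster, complement)
        assert res.p_value == pytest.approx(
            hypergeom_two_sided_p(int(a), int(b), int(c), int(d)), abs=1e-12
        )


def test_printed_support_arithmetic():
    # supports of 29.2% in-cluster and 13.4% in-complement give ~+117.9%
    assert relative_enrichment_pct(0.292, 0.134) == pytest.approx(117.91, abs=0.01)


def test_bonferroni_arithmetic():
    assert bonferroni_threshold(0.01, 50, 2) == pytest.approx(1e-4)
    assert bonferroni_threshold(0.01, 1, 1) == pytest.approx(0.01)
    assert bonferroni_threshold(0.01, 10, 3) != bonferroni_threshold(0.01, 20, 3)
    with pytest.raises(SizingError):
        bonferroni_threshold(0.01, 0, 2)


def test_bonferroni_never_adds_discoveries():
    rng = np.random.default_rng(2)
    transactions = [{f"c{i}" for i in range(8) if rng.random() < 0.3}
                    for _ in range(120)]
    labels = Clustering(rng.integers(0, 2, size=120), k=2,
                        medoid_indices=np.empty(0, int), seed=0)
    admissions = [Admission(f"a{i}", 50.0, 0,
                            [Observation("x", 0.0, 1.0)],
                            [CodeEntry(c, "diagnosis") for c in t])
                  for i, t in enumerate(transactions)]
    enr = enrich_clustering(labels, admissions, "diagnosis",
                            EnrichmentConfig(alpha=0.05, min_support=0.05))
    for ce in enr.values():
        n_corrected = sum(r.significant for r in ce.prevalent)
        n_uncorrected = sum(r.p_value <= 0.05 for r in ce.prevalent)
        assert n_corrected <= n_uncorrected


# -- planted-signal recovery ------------------------------------------------


def test_planted_code_recovered_with_truth_labels():
    cfg = SimulationConfig(
        n_admissions=1000,
        obs_count_lognormal=(2.0, 0.3),
        enrichment_multiplier=3.0,
        baseline_code_prob=0.08,
        seed=6,
    )
    cohort, truth = generate_cohort(cfg)
    labels = Clustering(truth_labels(truth, cohort.admission_ids()),
                        k=cfg.n_subgroups, medoid_indices=np.empty(0, int), seed=0)
    enr = enrich_clustering(labels, cohort.admissions, "diagnosis",
                            EnrichmentConfig(alpha=0.01, min_support=0.05))
    for g in range(cfg.n_subgroups):
        planted = {c for c in truth.subgroup_codes[g] if "." in c}
        hits = {
            code
            for r in enr[g].enriched
            if r.direction == "positive" and r.significant
            for code in r.itemset.codes
        }
        diag_planted = {c for c in planted
                        if any(e.code == c and e.kind == "diagnosis"
                               for a in cohort.admissions for e in a.codes)}
        assert diag_planted & hits


def test_whole_population_cluster_has_no_complement():
    admissions = [Admission(f"a{i}", 50.0, 0, [Observation("x", 0.0, 1.0)],
                            [CodeEntry("401.9", "diagnosis")])
                  for i in range(10)]
    labels = Clustering(np.zeros(10, int), k=1,
                        medoid_indices=np.empty(0, int), seed=0)
    with pytest.raises(Exception):
        enrich_clustering(labels, admissions, "diagnosis",
                          EnrichmentConfig(min_support=0.5))


def test_uniform_code_direction_none():
    admissions = [Admission(f"a{i}", 50.0, 0, [Observation("x", 0.0, 1.0)],
                            [CodeEntry("401.9", "diagnosis")])
                  for i in range(20)]
    labels = Clustering(np.array([0] * 10 + [1] * 10), k=2,
                        medoid_indices=np.empty(0, int), seed=0)
    enr = enrich_clustering(labels, admissions, "diagnosis",
                            EnrichmentConfig(min_support=0.5))
    for ce in enr.values():
        assert all(r.direction == "none" for r in ce.prevalent)
        assert ce.enriched == []


# -- ICD chapters -----------------------------------------------------------


def test_icd_chapter_lookup():
    assert icd9_chapter("486") == "Respiratory system"
    assert icd9_chapter("518.8") == "Respiratory system"
    assert icd9_chapter("V58.6").startswith("Supplementary")
    assert icd9_chapter("E933.1").startswith("External")
    assert icd9_chapter("garbage") == "unknown"


def test_category_counts_every_occurrence():
    adm = Admission("a", 50.0, 0, [Observation("x", 0.0, 1.0)],
                    [CodeEntry("486", "diagnosis"), CodeEntry("518.8", "diagnosis"),
                     CodeEntry("401.9", "diagnosis"),
                     CodeEntry("96.04", "procedure")])
    counts = icd_category_counts([adm])
    assert counts["Respiratory system"] == 2
    assert counts["Circulatory system"] == 1
    # procedures are not diagnosis occurrences
    assert sum(counts.values()) == 3


def test_category_counts_empty():
    counts = icd_category_counts([])
    assert all(v == 0 for v in counts.values())
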