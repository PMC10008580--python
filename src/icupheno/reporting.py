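"""Cluster descriptive statistics, error/mortality binning, and the pipeline.

``run_pipeline`` chains the full method: cohort loading (or simulation) ->
admission and attribute selection -> train/validation split -> quantile
normalization and matrix assembly -> autoencoder training -> feature
extraction -> robust k-medoids clustering -> code enrichment -> reports.
Every stage draws its randomness from one master seed, and each stage's
artifacts are written before the next stage runs, so a failure aborts with the
stage name while earlier artifacts persist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoder import (GRUAutoencoder, ModelHyperparams, TrainConfig, encode,
                          reconstruct, reconstruction_metrics, train)
from .clustering import Clustering, find_robust_clusterings
from .cohort import Cohort, filter_admissions, read_cohort, select_attributes, \
    split_train_val, write_cohort
from .enrichment import EnrichmentConfig, enrich_clustering, icd_category_counts
from .preprocess import build_matrices, fit_normalizer
from .synthetic import SimulationConfig, generate_cohort
from .time_encoding import TemporalEncodingConfig

logger = logging.getLogger("icupheno")


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation; NaNs for empty input."""
    if values.size == 0:
        return float("nan"), float("nan"), float("nan")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class ClusterReport:
    table: pd.DataFrame  # one row per cluster

    def total_n(self) -> int:
        return int(self.table["n"].sum())


def cluster_descriptives(clustering: Clustering, admissions: list) -> ClusterReport:
    """Per-cluster N, % female, age and ICU-stay quartiles, 28-day mortality.

    ICU length of stay is summarized for all members and separately for
    survivors and deceased.  Empty clusters yield a row with N = 0 and NaN
    statistics.
    """
    if len(admissions) != clustering.labels.size:
        raise ValueError("labels are not aligned to the admission list")
    rows = []
    for c in range(clustering.k):
        members = [a for a, lab in zip(admissions, clustering.labels) if lab == c]
        if not members:
            rows.append({"cluster": c, "n": 0})
            continue
        ages = np.asarray([a.age_years for a in members])
        los = np.asarray([a.icu_los_days for a in members])
        dead = np.asarray([a.mortality_28d for a in members], dtype=bool)
        age_med, age_q1, age_q3 = _quartiles(ages)
        los_med, los_q1, los_q3 = _quartiles(los)
        surv_med, surv_q1, surv_q3 = _quartiles(los[~dead])
        dec_med, dec_q1, dec_q3 = _quartiles(los[dead])
        rows.append({
            "cluster": c,
            "n": len(members),
            "pct_female": float(np.mean([a.sex_index == 1 for a in members]) * 100),
            "age_median": age_med, "age_q1": age_q1, "age_q3": age_q3,
            "los_median": los_med, "los_q1": los_q1, "los_q3": los_q3,
            "los_survivors_median": surv_med, "los_survivors_q1": surv_q1,
            "los_survivors_q3": surv_q3,
            "los_deceased_median": dec_med, "los_deceased_q1": dec_q1,
            "los_deceased_q3": dec_q3,
            "mortality_28d": float(dead.mean()),
        })
    return ClusterReport(table=pd.DataFrame(rows))


def error_mortality_bins(per_admission_error: np.ndarray,
                         mortality_flags: np.ndarray, n_bins: int = 10,
                         trim_frac: float = 0.99) -> pd.DataFrame:
    """Bin admissions by reconstruction error; per bin, count and mortality.

    Keeps the bottom ``trim_frac`` of admissions by error (the extreme tail
    would otherwise dominate the bin range), then uses equal-width bins over
    the kept error range.
    """
    err = np.asarray(per_admission_error, dtype=float)
    mort = np.asarray(mortality_flags, dtype=bool)
    if err.shape != mort.shape:
        raise ValueError("error and mortality vectors must align")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    order = np.argsort(err, kind="stable")
    n_keep = int(np.floor(trim_frac * err.size))
    keep = order[:n_keep]
    err_k, mort_k = err[keep], mort[keep]

    lo, hi = float(err_k.min()), float(err_k.max())
    if lo == hi:  # degenerate: all kept errors identical -> one occupied bin
        edges = np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(err_k, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        count = int(in_bin.sum())
        rows.append({
            "bin_left": float(edges[b]), "bin_right": float(edges[b + 1]),
            "count": count,
            "mortality": float(mort_k[in_bin].mean()) if count else float("nan"),
        })
    out = pd.DataFrame(rows)
    assert out["count"].sum() == n_keep
    return out


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    cohort_dir: str | None = None
    out_dir: str = "icupheno_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    min_age: float = 22.0
    min_attr_support: float = 0.5
    train_frac: float = 0.9
    temporal: TemporalEncodingConfig = field(default_factory=TemporalEncodingConfig)
    model: ModelHyperparams = field(default_factory=ModelHyperparams)
    training: TrainConfig = field(default_factory=TrainConfig)
    k_values: tuple[int, ...] = (2, 3, 6)
    seeds_per_k: int = 1
    n_bootstrap: int = 10
    bootstrap_frac: float = 0.7
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    error_bins: int = 10
    error_trim_frac: float = 0.99
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimulationConfig(**kwargs["simulate"])
        if "temporal" in kwargs:
            kwargs["temporal"] = TemporalEncodingConfig(**kwargs["temporal"])
        if "model" in kwargs:
            kwargs["model"] = ModelHyperparams(**kwargs["model"])
        if "training" in kwargs:
            kwargs["training"] = TrainConfig(**kwargs["training"])
        if "enrichment" in kwargs:
            kwargs["enrichment"] = EnrichmentConfig(**kwargs["enrichment"])
        if "k_values" in kwargs:
            kwargs["k_values"] = tuple(kwargs["k_values"])
        if kwargs.get("cohort_dir") is None and kwargs.get("simulate") is None:
            raise ValueError("config must set either 'cohort_dir' or 'simulate'")
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute simulate/load -> preprocess -> train -> encode -> cluster ->
    enrich -> report; returns the artifacts directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            cohort, truth = generate_cohort(sim)
            write_cohort(cohort, out / "cohort")
            pd.DataFrame(
                {"admission_id": list(truth.labels),
                 "subgroup": list(truth.labels.values())}
            ).to_csv(out / "truth_labels.csv", index=False)
        elif config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
        else:
            raise ValueError("config must name a cohort_dir or a simulation")

        stage = "preprocess"
        cohort = filter_admissions(cohort, min_age=config.min_age)
        attributes = select_attributes(cohort, min_support=config.min_attr_support)
        train_ids, val_ids = split_train_val(cohort, config.train_frac,
                                             seed=config.seed)
        normalizer = fit_normalizer(cohort, train_ids, attributes)
        train_mats = build_matrices(cohort, attributes, normalizer,
                                    config.temporal, ids=train_ids)
        val_mats = build_matrices(cohort, attributes, normalizer,
                                  config.temporal, ids=val_ids)
        all_mats = build_matrices(cohort, attributes, normalizer, config.temporal)

        stage = "train"
        model = GRUAutoencoder(config.model, n_dynamic=len(attributes),
                               n_static=2, n_temporal=config.temporal.n_temporal,
                               seed=config.seed)
        tc = dataclasses.replace(config.training, seed=config.seed)
        model, history = train(model, train_mats, val_mats, tc)
        pd.DataFrame({k: v for k, v in history.items()
                      if isinstance(v, list)}).to_csv(out / "history.csv",
                                                      index=False)

        stage = "encode"
        features = encode(model, all_mats)
        feat_df = pd.DataFrame(
            features.embeddings,
            columns=[f"f{i:02d}" for i in range(features.embeddings.shape[1])],
        )
        feat_df.insert(0, "admission_id", features.admission_ids)
        feat_df.to_csv(out / "features.csv", index=False)

        recons = [reconstruct(model, m) for m in all_mats]
        report = reconstruction_metrics(all_mats, recons, normalizer)
        (out / "reconstruction.json").write_text(json.dumps({
            "median_mse": report.median_mse,
            "mape_percent": report.mape_percent,
        }, indent=2))

        stage = "cluster"
        survivors = find_robust_clusterings(
            features, k_values=list(config.k_values),
            seeds_per_k=config.seeds_per_k, n_b=config.n_bootstrap,
            sample_frac=config.bootstrap_frac, seed=config.seed,
        )
        label_rows, robust_rows = [], []
        for ci, (clustering, record) in enumerate(survivors):
            for aid, lab in zip(features.admission_ids, clustering.labels):
                label_rows.append({"admission_id": aid, "clustering_id": ci,
                                   "k": clustering.k, "label": int(lab)})
            for h in record.rob:
                robust_rows.append({"clustering_id": ci, "k": clustering.k,
                                    "metric": h, "rob": record.rob[h],
                                    "thresh": record.thresh[h],
                                    "robust": record.robust})
        pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False)
        pd.DataFrame(robust_rows).to_csv(out / "robustness.csv", index=False)

        stage = "enrich"
        ordered = [cohort.by_id(i) for i in features.admission_ids]
        for ci, (clustering, _) in enumerate(survivors):
            for kind in ("diagnosis", "procedure"):
                try:
                    enr = enrich_clustering(clustering, ordered, kind,
                                            config.enrichment)
                except ValueError as exc:
                    logger.warning("enrichment skipped for clustering %d (%s): %s",
                                   ci, kind, exc)
                    continue
                rows = []
                for c, ce in enr.items():
                    for r in ce.enriched:
                        rows.append({
                            "cluster": c,
                            "itemset": "|".join(r.itemset.sorted_codes()),
                            "support_cluster": r.support_cluster,
                            "support_complement": r.support_complement,
                            "relative_enrichment_pct": r.relative_enrichment_pct,
                            "p_value": r.p_value,
                            "direction": r.direction,
                            "significant": r.significant,
                        })
                pd.DataFrame(rows).to_csv(
                    out / f"enrichment_c{ci}_{kind}.csv", index=False)

        stage = "report"
        per_adm_err = np.asarray(
            [report.per_admission_error[i] for i in features.admission_ids])
        mortality = np.asarray([a.mortality_28d for a in ordered], dtype=bool)
        bins = error_mortality_bins(per_adm_err, mortality,
                                    n_bins=config.error_bins,
                                    trim_frac=config.error_trim_frac)
        bins.to_csv(out / "error_mortality_bins.csv", index=False)
        for ci, (clustering, _) in enumerate(survivors):
            desc = cluster_descriptives(clustering, ordered)
            desc.table.to_csv(out / f"descriptives_c{ci}.csv", index=False)
        cats = icd_category_counts(ordered)
        pd.DataFrame(sorted(cats.items()), columns=["chapter", "count"]).to_csv(
            out / "icd_categories.csv", index=False)
        if config.make_plots:
            _write_plots(out, bins, cats)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_admissions": len(cohort),
            "n_attributes": len(attributes),
            "n_robust_clusterings": len(survivors),
            "best_epoch": history.get("best_epoch"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _write_plots(out: Path, bins: pd.DataFrame, categories: dict[str, int]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (bins["bin_left"] + bins["bin_right"]) / 2
    width = (bins["bin_right"] - bins["bin_left"]).iloc[0]
    ax.bar(centers, bins["mortality"], width=width * 0.9)
    ax.set_xlabel("per-admission reconstruction error")
    ax.set_ylabel("28-day mortality")
    fig.tight_layout()
    fig.savefig(out / "error_mortality.png", dpi=120)
    plt.close(fig)

    nonzero = {k: v for k, v in categories.items() if v > 0}
    if nonzero:
        fig, ax = plt.subplots(figsize=(7, 0.3 * len(nonzero) + 1.5))
        names = list(nonzero)
        ax.barh(names, [nonzero[n] for n in names])
        ax.set_xlabel("diagnosis occurrences")
        fig.tight_layout()
        fig.savefig(out / "icd_categories.png", dpi=120)
        plt.close(fig)
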