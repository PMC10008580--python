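"""Built-in study-scale experiments on synthetic cohorts.

These bundle the full method — simulate, split, normalize, train, encode,
cluster — at a reduced problem size (300 admissions, short stays, 5 dynamic
attributes, GRU 32 / bottleneck 8) chosen so that a single CPU finishes one
training run in well under a minute.  The reduced runs use a larger learning
rate (0.003) than the full-scale default, which a model this small needs to
converge within its short epoch budget.  They are used to demonstrate, on
cohorts with known structure:

* **subgroup recovery** — k-medoids on the learned embeddings recovers the
  planted subgroups (adjusted Rand index against the ground truth);
* **ablation direction** — the model with sinusoidal positional encodings
  reaches a lower validation loss than the flat-minutes-only variant, since
  the planted signatures are anchored to absolute elapsed time;
* **bottleneck capacity** — widening the bottleneck does not worsen the
  achievable reconstruction loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .autoencoder import (GRUAutoencoder, ModelHyperparams, TrainConfig, encode,
                          reconstruct, reconstruction_metrics, train)
from .clustering import cluster_kmedoids
from .cohort import select_attributes, split_train_val
from .preprocess import build_matrices, fit_normalizer
from .synthetic import generate_cohort, reduced_test_config, truth_labels
from .time_encoding import TemporalEncodingConfig

REDUCED_HP = ModelHyperparams(gru_size=32, bottleneck_size=8)
REDUCED_LR = 0.003


@dataclass
class ReducedRun:
    seed: int
    n_pe: int
    best_val_loss: float
    n_epochs: int
    ari: float
    median_mse: float
    mape_percent: float


def run_reduced(seed: int, n_pe: int = 64, max_epochs: int = 25,
                n_admissions: int = 300, hp: ModelHyperparams = REDUCED_HP,
                learning_rate: float = REDUCED_LR,
                with_metrics: bool = False) -> ReducedRun:
    """One end-to-end reduced run; returns losses and subgroup-recovery ARI."""
    cfg = reduced_test_config(n_admissions=n_admissions, seed=seed)
    cohort, truth = generate_cohort(cfg)
    attributes = select_attributes(cohort)
    train_ids, val_ids = split_train_val(cohort, seed=seed)
    normalizer = fit_normalizer(cohort, train_ids, attributes)
    tcfg = TemporalEncodingConfig(n_pe=n_pe)
    train_mats = build_matrices(cohort, attributes, normalizer, tcfg, ids=train_ids)
    val_mats = build_matrices(cohort, attributes, normalizer, tcfg, ids=val_ids)

    model = GRUAutoencoder(hp, len(attributes), 2, tcfg.n_temporal, seed=seed)
    tc = TrainConfig(max_epochs=max_epochs, seed=seed, learning_rate=learning_rate)
    model, history = train(model, train_mats, val_mats, tc)

    all_mats = build_matrices(cohort, attributes, normalizer, tcfg)
    features = encode(model, all_mats)
    clustering = cluster_kmedoids(features, cfg.n_subgroups, seed=seed)
    ari = float(adjusted_rand_score(
        truth_labels(truth, features.admission_ids), clustering.labels
    ))

    median_mse = mape = float("nan")
    if with_metrics:
        recons = [reconstruct(model, m) for m in all_mats]
        report = reconstruction_metrics(all_mats, recons, normalizer)
        median_mse, mape = report.median_mse, report.mape_percent

    return ReducedRun(
        seed=seed, n_pe=n_pe, best_val_loss=float(history["best_val_loss"]),
        n_epochs=len(history["val_loss"]), ari=ari,
        median_mse=median_mse, mape_percent=mape,
    )


def subgroup_recovery(seeds=(0, 1, 2), **kwargs) -> dict:
    """Median adjusted Rand of k-medoids on embeddings vs planted truth."""
    runs = [run_reduced(s, **kwargs) for s in seeds]
    return {
        "runs": runs,
        "median_ari": float(np.median([r.ari for r in runs])),
        "median_val_loss": float(np.median([r.best_val_loss for r in runs])),
    }


def ablation_positional_encoding(seeds=(0, 1, 2), **kwargs) -> dict:
    """Positional-encoding model vs flat-minutes-only model, same data/seed."""
    pe_runs = [run_reduced(s, n_pe=64, **kwargs) for s in seeds]
    flat_runs = [run_reduced(s, n_pe=0, **kwargs) for s in seeds]
    pe_med = float(np.median([r.best_val_loss for r in pe_runs]))
    flat_med = float(np.median([r.best_val_loss for r in flat_runs]))
    return {
        "pe_runs": pe_runs,
        "flat_runs": flat_runs,
        "pe_median_val_loss": pe_med,
        "flat_median_val_loss": flat_med,
        "improvement_pct": (1.0 - pe_med / flat_med) * 100.0,
    }


def bottleneck_sweep(sizes=(2, 8, 46), seeds=(0, 1, 2), n_admissions: int = 120,
                     max_epochs: int = 10) -> dict[int, float]:
    """Median validation loss per bottleneck size on fixed small cohorts."""
    out = {}
    for size in sizes:
        hp = ModelHyperparams(gru_size=16, bottleneck_size=size)
        losses = [
            run_reduced(s, hp=hp, n_admissions=n_admissions,
                        max_epochs=max_epochs).best_val_loss
            for s in seeds
        ]
        out[size] = float(np.median(losses))
    return out
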