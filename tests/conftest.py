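import numpy as np
import pytest

from icupheno import (
    ModelHyperparams,
    TrainConfig,
    build_matrices,
    fit_normalizer,
    generate_cohort,
    reduced_test_config,
    select_attributes,
    split_train_val,
)
from icupheno.autoencoder import GRUAutoencoder
from icupheno.time_encoding import TemporalEncodingConfig


@pytest.fixture(scope="session")
def small_cohort():
    """60-admission reduced cohort shared by preprocessing/model tests."""
    cohort, truth = generate_cohort(reduced_test_config(n_admissions=60, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def prepared(small_cohort):
    """Attributes, split, normalizer and matrices for the small cohort."""
    cohort, truth = small_cohort
    attributes = select_attributes(cohort)
    train_ids, val_ids = split_train_val(cohort, seed=3)
    normalizer = fit_normalizer(cohort, train_ids, attributes)
    cfg = TemporalEncodingConfig(n_pe=8)
    matrices = build_matrices(cohort, attributes, normalizer, cfg)
    return {
        "cohort": cohort,
        "truth": truth,
        "attributes": attributes,
        "train_ids": train_ids,
        "val_ids": val_ids,
        "normalizer": normalizer,
        "temporal_cfg": cfg,
        "matrices": matrices,
    }


@pytest.fixture(scope="session")
def tiny_trained(prepared):
    """A briefly trained small model (3 epochs) for inference-contract tests."""
    attrs = prepared["attributes"]
    cfg = prepared["temporal_cfg"]
    by_id = {m.admission_id: m for m in prepared["matrices"]}
    train_mats = [by_id[i] for i in prepared["train_ids"]]
    val_mats = [by_id[i] for i in prepared["val_ids"]]
    hp = ModelHyperparams(gru_size=16, bottleneck_size=6, noise_sigma=0.05)
    model = GRUAutoencoder(hp, len(attrs), 2, cfg.n_temporal, seed=5)
    from icupheno import train as train_fn

    model, history = train_fn(
        model, train_mats, val_mats, TrainConfig(max_epochs=3, seed=5)
    )
    return model, history
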