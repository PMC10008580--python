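"""Quantile normalization, interpolation, and batch-assembly contracts."""

import numpy as np
import pytest

from icupheno import (
    Admission,
    Cohort,
    Observation,
    assemble_batch,
    build_matrix,
    fit_normalizer,
    pad_batch,
)
from icupheno.preprocess import NormalizerFitError
from icupheno.time_encoding import TemporalEncodingConfig


def _cohort_from_values(values, attr="x"):
    admissions = [
        Admission(f"a{i}", 50.0, 0, [Observation(attr, 0.0, float(v)),
                                     Observation(attr, 1.0, float(v) + 0.01)])
        for i, v in enumerate(values)
    ]
    return Cohort(admissions)


@pytest.fixture(scope="module")
def exp_normalizer():
    rng = np.random.default_rng(0)
    values = rng.exponential(scale=3.0, size=1000)  # 2 obs per admission -> 2000
    cohort = _cohort_from_values(values)
    ids = cohort.admission_ids()
    return cohort, fit_normalizer(cohort, ids, ["x"]), values


def test_transform_yields_standard_normal_marginal(exp_normalizer):
    cohort, norm, _ = exp_normalizer
    train_vals = np.asarray(
        [o.value for a in cohort.admissions for o in a.observations]
    )
    z = norm.transform("x", train_vals)
    assert abs(z.mean()) < 0.05
    assert abs(z.var() - 1.0) < 0.1


def test_transform_is_monotone(exp_normalizer):
    _, norm, values = exp_normalizer
    xs = np.sort(values)[:200]
    z = norm.transform("x", xs)
    assert np.all(np.diff(z) >= 0)


def test_training_median_maps_near_zero(exp_normalizer):
    cohort, norm, _ = exp_normalizer
    train_vals = np.asarray(
        [o.value for a in cohort.admissions for o in a.observations]
    )
    z_med = norm.transform("x", np.array([np.median(train_vals)]))[0]
    assert abs(z_med) < 0.05
    assert abs(norm.medians_normalized["x"]) < 0.05


def test_round_trip_bounded_by_quantile_spacing(exp_normalizer):
    _, norm, values = exp_normalizer
    sample = values[:100]
    back = norm.inverse_transform("x", norm.transform("x", sample))
    spacing = np.max(np.diff(np.sort(values)))
    assert np.max(np.abs(back - sample)) <= spacing


def test_out_of_range_values_clamp(exp_normalizer):
    cohort, norm, _ = exp_normalizer
    train_vals = np.asarray(
        [o.value for a in cohort.admissions for o in a.observations]
    )
    hi = norm.transform("x", np.array([train_vals.max() * 10.0]))[0]
    at_max = norm.transform("x", np.array([train_vals.max()]))[0]
    assert hi == pytest.approx(at_max)
    lo = norm.transform("x", np.array([-100.0]))[0]
    at_min = norm.transform("x", np.array([train_vals.min()]))[0]
    assert lo == pytest.approx(at_min)


def test_validation_data_cannot_change_fitted_map():
    rng = np.random.default_rng(1)
    base = rng.normal(size=500)
    cohort = _cohort_from_values(base)
    ids = cohort.admission_ids()
    train_ids = ids[:400]
    norm_a = fit_normalizer(cohort, train_ids, ["x"])
    # mutate only the held-out part of the cohort
    perturbed = _cohort_from_values(
        np.concatenate([base[:400], base[400:] + 50.0])
    )
    norm_b = fit_normalizer(perturbed, train_ids, ["x"])
    probe = np.linspace(base.min(), base.max(), 37)
    assert np.allclose(norm_a.transform("x", probe), norm_b.transform("x", probe))


def test_unfitted_attribute_is_lookup_error(exp_normalizer):
    _, norm, _ = exp_normalizer
    with pytest.raises(KeyError):
        norm.transform("nope", np.array([1.0]))


def test_fit_requires_observations():
    cohort = _cohort_from_values([1.0, 2.0])
    with pytest.raises(NormalizerFitError, match="ghost"):
        fit_normalizer(cohort, cohort.admission_ids(), ["x", "ghost"])


# -- matrix assembly --------------------------------------------------------


def _two_attr_admission():
    return Admission("m", 40.0, 1, [
        Observation("x", 0.0, 0.0), Observation("x", 10.0, 1.0),
        Observation("y", 5.0, 0.5),
    ])


@pytest.fixture(scope="module")
def simple_norm():
    # linear value grids make the quantile map affine on its fitted range, so
    # interpolation checks can be done in normalized space exactly
    admissions = [
        Admission(f"t{i}", 30.0 + i, 0, [Observation("x", 0.0, v),
                                         Observation("y", 1.0, v)])
        for i, v in enumerate(np.linspace(0.0, 1.0, 101))
    ]
    cohort = Cohort(admissions)
    return fit_normalizer(cohort, cohort.admission_ids(), ["x", "y"])


def test_linear_interpolation_at_union_grid_point(simple_norm):
    mat = build_matrix(_two_attr_admission(), ["x", "y"], simple_norm,
                       TemporalEncodingConfig(n_pe=4))
    assert np.array_equal(mat.times_min, [0.0, 5.0, 10.0])
    col_x = mat.values[:, 0]
    z0 = simple_norm.transform("x", np.array([0.0]))[0]
    z1 = simple_norm.transform("x", np.array([1.0]))[0]
    assert col_x[1] == pytest.approx((z0 + z1) / 2.0)  # midpoint in time
    # observed points are reproduced exactly
    assert col_x[0] == pytest.approx(z0)
    assert col_x[2] == pytest.approx(z1)


def test_unobserved_attribute_filled_with_train_median(simple_norm):
    adm = Admission("m", 40.0, 1, [Observation("x", 0.0, 0.3),
                                   Observation("x", 7.0, 0.6)])
    mat = build_matrix(adm, ["x", "y"], simple_norm, TemporalEncodingConfig(n_pe=4))
    assert np.allclose(mat.values[:, 1], simple_norm.medians_normalized["y"])


def test_union_grid_has_distinct_sorted_times(simple_norm):
    adm = Admission("m", 40.0, 0, [
        Observation("x", 3.0, 0.1), Observation("x", 7.5, 0.2),
        Observation("y", 7.0, 0.3),
    ])
    mat = build_matrix(adm, ["x", "y"], simple_norm, TemporalEncodingConfig(n_pe=4))
    assert np.array_equal(mat.times_min, [3.0, 7.0, 7.5])
    assert np.all(np.diff(mat.times_min) > 0)


def test_constant_extrapolation_outside_observed_range(simple_norm):
    adm = Admission("m", 40.0, 0, [
        Observation("x", 5.0, 0.4), Observation("x", 6.0, 0.8),
        Observation("y", 0.0, 0.5), Observation("y", 20.0, 0.5),
    ])
    mat = build_matrix(adm, ["x", "y"], simple_norm, TemporalEncodingConfig(n_pe=4))
    col_x = mat.values[:, 0]
    z4 = simple_norm.transform("x", np.array([0.4]))[0]
    z8 = simple_norm.transform("x", np.array([0.8]))[0]
    assert col_x[0] == pytest.approx(z4)   # before first observation
    assert col_x[-1] == pytest.approx(z8)  # after last observation


def test_static_block_repeats(simple_norm):
    mat = build_matrix(_two_attr_admission(), ["x", "y"], simple_norm,
                       TemporalEncodingConfig(n_pe=4))
    n_dyn = mat.schema.n_dynamic
    static = mat.values[:, n_dyn : n_dyn + 2]
    assert np.all(static == static[0])
    assert np.all(static[:, 1] == 1.0)  # raw sex index passes through


def test_build_matrix_requires_observations(simple_norm):
    adm = Admission("m", 40.0, 0, [Observation("other", 0.0, 1.0)])
    with pytest.raises(ValueError, match="no observations"):
        build_matrix(adm, ["x", "y"], simple_norm, TemporalEncodingConfig(n_pe=4))


def test_batch_padding_conservation(prepared):
    mats = prepared["matrices"][:4]
    x, mask = pad_batch(mats)
    lengths = [m.values.shape[0] for m in mats]
    assert x.shape[1] == max(lengths)
    assert mask.sum() == sum(lengths)
    for b, m in enumerate(mats):
        assert mask[b].sum() == m.values.shape[0]


def test_single_matrix_batch_has_no_padding(prepared):
    m = prepared["matrices"][0]
    x, mask = pad_batch([m])
    assert x.shape[1] == m.values.shape[0]
    assert mask.all()


def test_assemble_batch_partitions_all_matrices(prepared):
    mats = prepared["matrices"]
    batches = assemble_batch(mats, batch_size=4, rng=np.random.default_rng(0))
    seen = sorted(i for _, _, idx in batches for i in idx)
    assert seen == list(range(len(mats)))
    total_valid = sum(int(mask.sum()) for _, mask, _ in batches)
    assert total_valid == sum(m.values.shape[0] for m in mats)
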