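"""Quantile normalization, union-grid interpolation, and matrix assembly.

Normalization maps each attribute, independently, through its empirical
training-split quantiles and the standard-normal percent-point function, so
every attribute acquires an (approximately) zero-mean, unit-variance marginal
while staying robust to outliers.  The fit uses only the training split, and
the fitted map is then applied to all data so that validation values cannot
bias it.  Values outside the fitted range clamp to the fitted extremes.

Per admission, dynamic data becomes a matrix whose rows are the sorted union
of the admission's own observation times (no fixed-step resampling) and whose
columns are partitioned into dynamic | static | temporal blocks.  Dynamic
values are exact where observed, linearly interpolated in time between an
attribute's own flanking observations, constant (nearest observation) outside
its observed range, and the train-split median everywhere when the admission
never measured the attribute.  Static columns (normalized age, raw sex index)
repeat at every row; temporal columns come from the positional-time encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import QuantileTransformer

from .cohort import Admission, Cohort
from .time_encoding import TemporalEncodingConfig, temporal_features

logger = logging.getLogger("icupheno")

STATIC_COLUMNS = ("age", "sex")


class NormalizerFitError(ValueError):
    pass


def _fit_qt(values: np.ndarray) -> QuantileTransformer:
    qt = QuantileTransformer(
        n_quantiles=min(1000, len(values)),
        output_distribution="normal",
        subsample=1_000_000,
        random_state=0,
    )
    qt.fit(values.reshape(-1, 1))
    return qt


@dataclass
class Normalizer:
    """Per-attribute monotone quantile maps to a standard-normal marginal."""

    attribute_maps: dict[str, QuantileTransformer] = field(default_factory=dict)
    medians_normalized: dict[str, float] = field(default_factory=dict)
    age_map: QuantileTransformer | None = None
    time_map: QuantileTransformer | None = None
    fitted_on: list[str] = field(default_factory=list)

    def transform(self, attribute: str, values: np.ndarray) -> np.ndarray:
        if attribute not in self.attribute_maps:
            raise KeyError(f"attribute {attribute!r} was not fitted")
        v = np.asarray(values, dtype=float).reshape(-1, 1)
        return self.attribute_maps[attribute].transform(v).ravel()

    def inverse_transform(self, attribute: str, normalized: np.ndarray) -> np.ndarray:
        if attribute not in self.attribute_maps:
            raise KeyError(f"attribute {attribute!r} was not fitted")
        v = np.asarray(normalized, dtype=float).reshape(-1, 1)
        return self.attribute_maps[attribute].inverse_transform(v).ravel()

    def transform_age(self, ages: np.ndarray) -> np.ndarray:
        if self.age_map is None:
            raise KeyError("age map was not fitted")
        return self.age_map.transform(np.asarray(ages, float).reshape(-1, 1)).ravel()

    def transform_time(self, times_min: np.ndarray) -> np.ndarray:
        if self.time_map is None:
            raise KeyError("time map was not fitted")
        t = np.asarray(times_min, dtype=float)
        if t.size == 0:
            return np.empty(0)
        return self.time_map.transform(t.reshape(-1, 1)).ravel()


def fit_normalizer(
    cohort: Cohort, train_ids: list[str], attributes: list[str]
) -> Normalizer:
    """Fit per-attribute quantile maps and medians on the training split only."""
    train_set = set(train_ids)
    train_adms = [a for a in cohort.admissions if a.admission_id in train_set]
    if not train_adms:
        raise NormalizerFitError("no training admissions found in cohort")

    norm = Normalizer(fitted_on=list(train_ids))
    pooled_times: list[np.ndarray] = []
    per_attr: dict[str, list[float]] = {attr: [] for attr in attributes}
    for a in train_adms:
        times = []
        for o in a.observations:
            times.append(o.time_min)
            if o.attribute in per_attr:
                per_attr[o.attribute].append(o.value)
        pooled_times.append(np.asarray(times))

    for attr in attributes:
        values = np.asarray(per_attr[attr], dtype=float)
        if values.size == 0:
            raise NormalizerFitError(
                f"attribute {attr!r} has no observations in the training split"
            )
        if np.unique(values).size < 2:
            raise NormalizerFitError(
                f"attribute {attr!r} needs >= 2 distinct training values"
            )
        qt = _fit_qt(values)
        norm.attribute_maps[attr] = qt
        median = float(np.median(values))
        norm.medians_normalized[attr] = float(
            qt.transform(np.array([[median]]))[0, 0]
        )

    ages = np.asarray([a.age_years for a in train_adms], dtype=float)
    norm.age_map = _fit_qt(ages)
    all_times = np.concatenate(pooled_times) if pooled_times else np.empty(0)
    norm.time_map = _fit_qt(all_times)
    return norm


@dataclass(frozen=True)
class ColumnSchema:
    """Fixed ordering of matrix columns: dynamic | static | temporal."""

    dynamic: tuple[str, ...]
    static: tuple[str, ...]
    temporal: tuple[str, ...]

    @property
    def n_dynamic(self) -> int:
        return len(self.dynamic)

    @property
    def n_static(self) -> int:
        return len(self.static)

    @property
    def n_temporal(self) -> int:
        return len(self.temporal)

    @property
    def n_columns(self) -> int:
        return self.n_dynamic + self.n_static + self.n_temporal

    @property
    def n_reconstructed(self) -> int:
        # the model reconstructs dynamic + static columns; temporal columns
        # are inputs only
        return self.n_dynamic + self.n_static

    def all_names(self) -> tuple[str, ...]:
        return self.dynamic + self.static + self.temporal


@dataclass
class AdmissionMatrix:
    admission_id: str
    times_min: np.ndarray  # (G,) strictly increasing among valid rows
    values: np.ndarray  # (G, n_columns)
    mask: np.ndarray  # (G,) bool; False rows are padding
    schema: ColumnSchema

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def build_matrix(
    admission: Admission,
    attributes: list[str],
    normalizer: Normalizer,
    temporal_cfg: TemporalEncodingConfig | None = None,
) -> AdmissionMatrix:
    """Assemble one admission's padded-free, fully valid matrix.

    The grid is the sorted union of the admission's observation times over the
    selected attributes; duplicate (attribute, time) pairs keep the last value.
    """
    temporal_cfg = temporal_cfg or TemporalEncodingConfig()
    selected = [o for o in admission.observations if o.attribute in set(attributes)]
    if not selected:
        raise ValueError(
            f"admission {admission.admission_id!r} has no observations among the "
            "selected attributes; it should have been filtered out"
        )

    grid = np.unique(np.asarray([o.time_min for o in selected], dtype=float))
    n_dyn = len(attributes)
    dynamic = np.empty((grid.size, n_dyn), dtype=float)

    for j, attr in enumerate(attributes):
        obs = [(o.time_min, o.value) for o in selected if o.attribute == attr]
        if not obs:
            dynamic[:, j] = normalizer.medians_normalized[attr]
            continue
        by_time: dict[float, float] = {}
        for t, v in obs:  # last-read value wins on duplicates
            by_time[t] = v
        t_obs = np.asarray(sorted(by_time), dtype=float)
        v_obs = normalizer.transform(attr, np.asarray([by_time[t] for t in t_obs]))
        # linear in time between flanking observations; constant beyond range
        dynamic[:, j] = np.interp(grid, t_obs, v_obs)

    age_norm = float(normalizer.transform_age(np.array([admission.age_years]))[0])
    static = np.column_stack(
        [
            np.full(grid.size, age_norm),
            np.full(grid.size, float(admission.sex_index)),
        ]
    )
    temporal = temporal_features(grid, normalizer, temporal_cfg)

    schema = ColumnSchema(
        dynamic=tuple(attributes),
        static=STATIC_COLUMNS,
        temporal=tuple(temporal_cfg.column_names()),
    )
    values = np.concatenate([dynamic, static, temporal], axis=1)
    return AdmissionMatrix(
        admission_id=admission.admission_id,
        times_min=grid,
        values=values,
        mask=np.ones(grid.size, dtype=bool),
        schema=schema,
    )


def build_matrices(
    cohort: Cohort,
    attributes: list[str],
    normalizer: Normalizer,
    temporal_cfg: TemporalEncodingConfig | None = None,
    ids: list[str] | None = None,
) -> list[AdmissionMatrix]:
    ids = ids if ids is not None else cohort.admission_ids()
    by_id = {a.admission_id: a for a in cohort.admissions}
    return [
        build_matrix(by_id[i], attributes, normalizer, temporal_cfg) for i in ids
    ]


def pad_batch(matrices: list[AdmissionMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Pad matrices with mask=False rows to the longest length in the batch.

    Returns ``(X, M)`` with ``X`` of shape (B, T_max, n_columns) and boolean
    mask ``M`` of shape (B, T_max).
    """
    if not matrices:
        raise ValueError("cannot pad an empty batch")
    t_max = max(m.values.shape[0] for m in matrices)
    n_col = matrices[0].values.shape[1]
    x = np.zeros((len(matrices), t_max, n_col), dtype=float)
    mask = np.zeros((len(matrices), t_max), dtype=bool)
    for b, m in enumerate(matrices):
        g = m.values.shape[0]
        x[b, :g] = m.values
        mask[b, :g] = m.mask
    return x, mask


def assemble_batch(
    matrices: list[AdmissionMatrix],
    batch_size: int = 4,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray, list[int]]]:
    """Group matrices into padded mini-batches.

    With an ``rng`` the batch order (and membership) is seeded-random, as used
    per training epoch; without one the input order is kept.  Each batch is
    ``(X, mask, indices)`` where indices refer to positions in ``matrices``.
    """
    if not matrices:
        raise ValueError("cannot assemble batches from an empty list")
    order = np.arange(len(matrices))
    if rng is not None:
        order = rng.permutation(len(matrices))
    batches = []
    for start in range(0, len(order), batch_size):
        idx = [int(i) for i in order[start : start + batch_size]]
        x, mask = pad_batch([matrices[i] for i in idx])
        batches.append((x, mask, idx))
    return batches
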