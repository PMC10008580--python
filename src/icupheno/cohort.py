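"""Cohort data model, delimited-file I/O, and admission/attribute selection.

The unit of analysis is an ICU *admission*: one stay of one patient, carrying
static attributes (age in years as a float, sex as a 0/1 index), a list of
timestamped numeric observations (time expressed as minutes since the start of
the admission), a list of ICD-9-style diagnosis/procedure codes, a 28-day
mortality flag, and the ICU length of stay in days.  Multiple stays of the same
patient are deliberately treated as distinct admissions.

A cohort is serialized as three UTF-8 delimited files with a header row:

* ``admissions``:   admission_id, age_years, sex, mortality_28d, icu_los_days
* ``observations``: admission_id, attribute, time_min, value
* ``codes``:        admission_id, code, kind, label      (optional file)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("icupheno")

DIAGNOSIS = "diagnosis"
PROCEDURE = "procedure"


class CohortIntegrityError(ValueError):
    """Raised when cohort files are mutually inconsistent."""


class SizingError(ValueError):
    """Raised when an operation receives too little data to be meaningful."""


@dataclass(frozen=True)
class Observation:
    """One timestamped measurement of one attribute."""

    attribute: str
    time_min: float
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_min) or self.time_min < 0:
            raise ValueError(
                f"observation time must be a non-negative finite number of minutes, "
                f"got {self.time_min!r} for attribute {self.attribute!r}"
            )
        if not np.isfinite(self.value):
            raise ValueError(f"observation value must be finite, got {self.value!r}")


@dataclass(frozen=True)
class CodeEntry:
    code: str
    kind: str  # "diagnosis" | "procedure"
    label: str = ""


@dataclass
class Admission:
    """One ICU stay: static data, dynamic observations, codes and outcome."""

    admission_id: str
    age_years: float
    sex_index: int
    observations: list[Observation] = field(default_factory=list)
    codes: list[CodeEntry] = field(default_factory=list)
    mortality_28d: bool = False
    icu_los_days: float = 0.0

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"age_years must be positive, got {self.age_years}")
        if self.sex_index not in (0, 1):
            raise ValueError(f"sex_index must be 0 or 1, got {self.sex_index}")

    def observations_for(self, attribute: str) -> list[Observation]:
        return [o for o in self.observations if o.attribute == attribute]

    def attribute_names(self) -> set[str]:
        return {o.attribute for o in self.observations}

    def code_set(self, kind: str | None = None) -> set[str]:
        return {c.code for c in self.codes if kind is None or c.kind == kind}


@dataclass
class Cohort:
    """Ordered collection of admissions plus the attribute catalogue."""

    admissions: list[Admission]
    attribute_catalogue: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [a.admission_id for a in self.admissions]
        if len(ids) != len(set(ids)):
            raise CohortIntegrityError("admission ids are not unique")
        observed = set()
        for a in self.admissions:
            observed |= a.attribute_names()
        self.attribute_catalogue = set(self.attribute_catalogue) | observed

    def __len__(self) -> int:
        return len(self.admissions)

    def admission_ids(self) -> list[str]:
        return [a.admission_id for a in self.admissions]

    def by_id(self, admission_id: str) -> Admission:
        for a in self.admissions:
            if a.admission_id == admission_id:
                return a
        raise KeyError(admission_id)


@dataclass(frozen=True)
class CollisionRule:
    """Resolution of a label collision: fuse attributes or split one apart.

    ``merge`` concatenates several source series into one target attribute.
    ``split`` routes every observation of one source attribute to exactly one
    of several targets using per-target predicates over the observation; the
    predicates must be disjoint and exhaustive.
    """

    rule_kind: str  # "merge" | "split"
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    predicates: tuple[Callable[[Observation], bool], ...] = ()

    def __post_init__(self) -> None:
        if self.rule_kind == "merge":
            if len(self.sources) < 2 or len(self.targets) != 1:
                raise ValueError("merge rule needs >=2 sources and exactly 1 target")
        elif self.rule_kind == "split":
            if len(self.sources) != 1 or len(self.targets) < 2:
                raise ValueError("split rule needs 1 source and >=2 targets")
            if len(self.predicates) != len(self.targets):
                raise ValueError("split rule needs one predicate per target")
        else:
            raise ValueError(f"unknown rule_kind {self.rule_kind!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ADMISSION_COLS = ["admission_id", "age_years", "sex", "mortality_28d", "icu_los_days"]
_OBSERVATION_COLS = ["admission_id", "attribute", "time_min", "value"]
_CODE_COLS = ["admission_id", "code", "kind", "label"]


def _paths(base: str | Path) -> dict[str, Path]:
    base = Path(base)
    return {
        "admissions": base / "admissions.csv",
        "observations": base / "observations.csv",
        "codes": base / "codes.csv",
    }


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the three-file cohort representation; returns the file paths."""
    paths = _paths(directory)
    paths["admissions"].parent.mkdir(parents=True, exist_ok=True)

    adm = pd.DataFrame(
        [
            {
                "admission_id": a.admission_id,
                "age_years": a.age_years,
                "sex": a.sex_index,
                "mortality_28d": int(a.mortality_28d),
                "icu_los_days": a.icu_los_days,
            }
            for a in cohort.admissions
        ],
        columns=_ADMISSION_COLS,
    )
    obs = pd.DataFrame(
        [
            {
                "admission_id": a.admission_id,
                "attribute": o.attribute,
                "time_min": o.time_min,
                "value": o.value,
            }
            for a in cohort.admissions
            for o in a.observations
        ],
        columns=_OBSERVATION_COLS,
    )
    codes = pd.DataFrame(
        [
            {
                "admission_id": a.admission_id,
                "code": c.code,
                "kind": c.kind,
                "label": c.label,
            }
            for a in cohort.admissions
            for c in a.codes
        ],
        columns=_CODE_COLS,
    )
    adm.to_csv(paths["admissions"], index=False)
    obs.to_csv(paths["observations"], index=False)
    codes.to_csv(paths["codes"], index=False)
    return paths


def read_cohort(directory: str | Path) -> Cohort:
    """Read the three-file cohort representation written by :func:`write_cohort`.

    The codes file is optional; if it is absent the cohort loads with empty
    code lists and a warning.  Unknown columns are ignored with a warning.
    Observations referencing a missing admission id raise an integrity error,
    and negative observation times raise a validation error.
    """
    paths = _paths(directory)
    if not paths["admissions"].exists():
        raise FileNotFoundError(paths["admissions"])
    if not paths["observations"].exists():
        raise FileNotFoundError(paths["observations"])

    adm = pd.read_csv(paths["admissions"], dtype={"admission_id": str})
    obs = pd.read_csv(paths["observations"], dtype={"admission_id": str})
    for df, expected, name in ((adm, _ADMISSION_COLS, "admissions"),
                               (obs, _OBSERVATION_COLS, "observations")):
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise CohortIntegrityError(f"{name} file lacks columns {missing}")
        extra = [c for c in df.columns if c not in expected]
        if extra:
            logger.warning("ignoring unknown columns %s in %s file", extra, name)

    if paths["codes"].exists():
        codes = pd.read_csv(
            paths["codes"], dtype={"admission_id": str, "code": str}
        ).fillna({"label": ""})
    else:
        logger.warning("codes file %s absent; loading cohort without codes", paths["codes"])
        codes = pd.DataFrame(columns=_CODE_COLS)

    known_ids = set(adm["admission_id"])
    bad = set(obs["admission_id"]) - known_ids
    if bad:
        raise CohortIntegrityError(
            f"observations reference unknown admission ids: {sorted(bad)[:5]}"
        )
    if (obs["time_min"] < 0).any():
        raise ValueError("observations file contains negative time_min values")

    obs_by_id: dict[str, list[Observation]] = {aid: [] for aid in known_ids}
    for row in obs.itertuples(index=False):
        obs_by_id[row.admission_id].append(
            Observation(str(row.attribute), float(row.time_min), float(row.value))
        )
    codes_by_id: dict[str, list[CodeEntry]] = {aid: [] for aid in known_ids}
    for row in codes.itertuples(index=False):
        if row.admission_id in codes_by_id:
            codes_by_id[row.admission_id].append(
                CodeEntry(str(row.code), str(row.kind), str(row.label))
            )

    admissions = [
        Admission(
            admission_id=str(r.admission_id),
            age_years=float(r.age_years),
            sex_index=int(r.sex),
            observations=obs_by_id[str(r.admission_id)],
            codes=codes_by_id[str(r.admission_id)],
            mortality_28d=bool(r.mortality_28d),
            icu_los_days=float(r.icu_los_days),
        )
        for r in adm.itertuples(index=False)
    ]
    return Cohort(admissions=admissions)


# ---------------------------------------------------------------------------
# Label-collision resolution
# ---------------------------------------------------------------------------


def resolve_collisions(cohort: Cohort, rules: Sequence[CollisionRule]) -> Cohort:
    """Apply merge/split rules to every admission's observations.

    Merging concatenates the source series and re-sorts by time; splitting
    routes each observation of the source attribute to exactly one target.
    The total observation count is conserved.  Non-exhaustive split predicates
    raise an error naming the unrouted observation.
    """
    new_admissions = []
    for a in cohort.admissions:
        observations = list(a.observations)
        for rule in rules:
            if rule.rule_kind == "merge":
                target = rule.targets[0]
                merged = [
                    Observation(target, o.time_min, o.value)
                    for o in observations
                    if o.attribute in rule.sources
                ]
                rest = [o for o in observations if o.attribute not in rule.sources]
                merged.sort(key=lambda o: o.time_min)
                observations = rest + merged
            else:  # split
                source = rule.sources[0]
                routed = []
                for o in observations:
                    if o.attribute != source:
                        routed.append(o)
                        continue
                    hits = [t for t, p in zip(rule.targets, rule.predicates) if p(o)]
                    if not hits:
                        raise ValueError(
                            f"split rule for {source!r} routed no target for observation "
                            f"(t={o.time_min}, v={o.value}) of admission {a.admission_id!r}"
                        )
                    routed.append(Observation(hits[0], o.time_min, o.value))
                observations = routed
        new_admissions.append(replace(a, observations=observations))
    out = Cohort(admissions=new_admissions)
    assert sum(len(x.observations) for x in out.admissions) == sum(
        len(x.observations) for x in cohort.admissions
    )
    return out


# ---------------------------------------------------------------------------
# Admission selection, attribute support, split
# ---------------------------------------------------------------------------


def filter_admissions(cohort: Cohort, min_age: float = 22.0) -> Cohort:
    """Keep admissions aged ``min_age`` and up that have any dynamic data.

    The age boundary is inclusive; repeated admissions of one patient are kept
    as distinct admissions; order is preserved.
    """
    kept = [
        a
        for a in cohort.admissions
        if a.age_years >= min_age and len(a.observations) > 0
    ]
    return Cohort(admissions=kept)


def attribute_support(cohort: Cohort) -> dict[str, float]:
    """Fraction of admissions with at least one observation of each attribute."""
    if len(cohort) == 0:
        raise SizingError("cannot compute attribute support on an empty cohort")
    counts: dict[str, int] = {attr: 0 for attr in cohort.attribute_catalogue}
    for a in cohort.admissions:
        for attr in a.attribute_names():
            counts[attr] += 1
    n = len(cohort)
    return {attr: c / n for attr, c in counts.items()}


def select_attributes(cohort: Cohort, min_support: float = 0.5) -> list[str]:
    """Attributes whose support is at least ``min_support`` (inclusive).

    Sorted by descending support, ties broken by name, so the returned column
    order is deterministic.
    """
    support = attribute_support(cohort)
    selected = [a for a, s in support.items() if s >= min_support]
    return sorted(selected, key=lambda a: (-support[a], a))


def split_train_val(
    cohort: Cohort, train_frac: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded random split of admission ids into disjoint train/validation sets.

    Train size is ``round(train_frac * N)``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    ids = cohort.admission_ids()
    if len(ids) < 2:
        raise SizingError("need at least 2 admissions to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = [ids[i] for i in sorted(order[:n_train])]
    val = [ids[i] for i in sorted(order[n_train:])]
    return train, val


def dedupe_observations(admission: Admission) -> Admission:
    """Resolve duplicate (attribute, time) observations, keeping the last read."""
    seen: dict[tuple[str, float], int] = {}
    for i, o in enumerate(admission.observations):
        key = (o.attribute, o.time_min)
        if key in seen:
            logger.warning(
                "admission %s: duplicate observation of %r at t=%s; keeping last",
                admission.admission_id, o.attribute, o.time_min,
            )
        seen[key] = i
    kept = [admission.observations[i] for i in sorted(seen.values())]
    return replace(admission, observations=kept)
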