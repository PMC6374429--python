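"""Domain types and CSV readers/writers for longitudinal multi-modal cohorts.

A cohort is a set of study participants, each carrying a baseline diagnosis
(``CN`` cognitively normal, ``MCI`` mild cognitive impairment, ``AD``
Alzheimer's disease), an optional conversion month (MCI only), a follow-up
length, and per-modality visit sequences.  A modality sequence is an ordered
set of visit months from baseline with one fully observed feature row per
visit; a modality a subject never contributed is simply absent, never an
all-NaN row.  Cross-sectional modalities (demographics, MRI phenotypes) are
treated as length-one sequences so a single recurrent encoder interface
covers everything.

On-disk format is two plain CSV files: a long-format visit table
``(subject_id, modality, visit_month, f1..fk)`` with trailing feature columns
left empty for narrower modalities, and a subject table
``(subject_id, baseline_group, conversion_month, followup_month)``.  The
modality registry travels as a small YAML/JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

GROUPS = ("CN", "MCI", "AD")

__all__ = [
    "GROUPS",
    "ModalitySpec",
    "ModalitySequence",
    "Subject",
    "Cohort",
    "default_registry",
    "read_cohort",
    "write_cohort",
    "load_cohort",
    "read_registry",
    "write_registry",
]


class CohortError(ValueError):
    """Raised when cohort data violates a structural invariant."""


@dataclass(frozen=True)
class ModalitySpec:
    """One modality of the study: feature width, encoder width, temporality.

    The default registry mirrors the study design: composite cognitive
    scores (memory + executive function), demographics (age, sex, education,
    APOE e4), CSF analytes, and MRI-derived phenotypes.
    """

    name: str
    n_features: int
    hidden_dim: int
    longitudinal: bool

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortError("modality name must be non-empty")
        if self.n_features < 1:
            raise CohortError(f"{self.name}: n_features must be >= 1")
        if self.hidden_dim < 1:
            raise CohortError(f"{self.name}: hidden_dim must be >= 1")


def default_registry() -> list[ModalitySpec]:
    """Stock four-modality registry with the study's widths and encoder sizes.

    CSF is kept at five features and MRI at three even though only three
    analytes (Abeta1-42, t-tau, p-tau) and two imaging phenotypes
    (hippocampal volume, entorhinal thickness) are individually named in the
    study description; the extra columns are unexplained there (plausibly
    derived ratios) and are retained for shape fidelity.
    """
    return [
        ModalitySpec("cognitive", n_features=2, hidden_dim=3, longitudinal=True),
        ModalitySpec("demographics", n_features=4, hidden_dim=5, longitudinal=False),
        ModalitySpec("csf", n_features=5, hidden_dim=6, longitudinal=True),
        ModalitySpec("mri", n_features=3, hidden_dim=4, longitudinal=False),
    ]


@dataclass
class ModalitySequence:
    """Ordered visits of one modality for one subject.

    ``visit_months`` are real months from baseline (baseline = 0), strictly
    increasing; ``observations`` is a dense (T, n_features) matrix with no
    missing entries — a wholly missing visit is simply not a row.
    """

    modality: str
    visit_months: np.ndarray
    observations: np.ndarray

    def __post_init__(self) -> None:
        self.visit_months = np.asarray(self.visit_months, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float)
        if self.visit_months.ndim != 1 or self.visit_months.size < 1:
            raise CohortError(f"{self.modality}: need at least one visit")
        if self.observations.ndim != 2:
            raise CohortError(f"{self.modality}: observations must be 2-D (T, F)")
        if self.observations.shape[0] != self.visit_months.size:
            raise CohortError(
                f"{self.modality}: {self.observations.shape[0]} observation rows "
                f"for {self.visit_months.size} visits"
            )
        if np.any(self.visit_months < 0):
            raise CohortError(f"{self.modality}: visit months must be >= 0")
        if np.any(np.diff(self.visit_months) <= 0):
            raise CohortError(f"{self.modality}: visit months must be strictly increasing")
        if not np.all(np.isfinite(self.observations)):
            raise CohortError(f"{self.modality}: observations contain NaN/inf")

    @property
    def length(self) -> int:
        return int(self.visit_months.size)

    def truncated_to_first_visit(self) -> "ModalitySequence":
        return ModalitySequence(self.modality, self.visit_months[:1], self.observations[:1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModalitySequence):
            return NotImplemented
        return (
            self.modality == other.modality
            and np.array_equal(self.visit_months, other.visit_months)
            and np.array_equal(self.observations, other.observations)
        )


@dataclass
class Subject:
    """One participant: diagnosis, conversion/follow-up times, sequences."""

    id: str
    baseline_group: str
    conversion_month: float | None
    followup_month: float
    sequences: dict[str, ModalitySequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_group not in GROUPS:
            raise CohortError(f"{self.id}: unknown group {self.baseline_group!r}")
        if self.followup_month < 0:
            raise CohortError(f"{self.id}: followup_month must be >= 0")
        if self.conversion_month is not None:
            if self.baseline_group != "MCI":
                raise CohortError(
                    f"{self.id}: conversion_month only valid for MCI subjects"
                )
            if self.conversion_month > self.followup_month:
                raise CohortError(
                    f"{self.id}: conversion_month exceeds followup_month"
                )
        if not self.sequences:
            raise CohortError(f"{self.id}: at least one modality sequence required")
        for name, seq in self.sequences.items():
            if name != seq.modality:
                raise CohortError(f"{self.id}: sequence keyed {name} is for {seq.modality}")

    @property
    def is_converter(self) -> bool:
        return self.conversion_month is not None

    def has_modality(self, name: str) -> bool:
        return name in self.sequences


@dataclass
class Cohort:
    """A validated set of subjects plus the modality registry they conform to."""

    subjects: list[Subject]
    registry: list[ModalitySpec]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject ids: {dupes}")
        specs = self.registry_by_name
        for s in self.subjects:
            for name, seq in s.sequences.items():
                if name not in specs:
                    raise CohortError(f"{s.id}: modality {name!r} not in registry")
                spec = specs[name]
                if seq.observations.shape[1] != spec.n_features:
                    raise CohortError(
                        f"{s.id}/{name}: {seq.observations.shape[1]} features, "
                        f"registry says {spec.n_features}"
                    )
                if not spec.longitudinal and seq.length != 1:
                    raise CohortError(
                        f"{s.id}/{name}: non-longitudinal modality must have T = 1"
                    )

    @property
    def registry_by_name(self) -> dict[str, ModalitySpec]:
        return {spec.name: spec for spec in self.registry}

    def subjects_in_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.baseline_group == group]

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def restrict(self, ids: Iterable[str]) -> "Cohort":
        """Sub-cohort containing only the given subject ids (order preserved)."""
        keep = set(ids)
        return Cohort([s for s in self.subjects if s.id in keep], self.registry)

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# CSV I/O

def _feature_columns(registry: list[ModalitySpec]) -> list[str]:
    k = max(spec.n_features for spec in registry)
    return [f"f{i + 1}" for i in range(k)]


def read_cohort(
    visit_table: str | Path,
    subject_table: str | Path,
    registry: list[ModalitySpec],
) -> Cohort:
    """Read a cohort from long-format visit and subject CSV files.

    Visit rows may arrive in any order; sequences emerge sorted by visit
    month.  Duplicate (subject, modality, month) rows and feature-count
    mismatches against the registry are hard errors naming the offender.
    """
    specs = {spec.name: spec for spec in registry}
    visits = pd.read_csv(visit_table, float_precision="round_trip")
    subjects_df = pd.read_csv(
        subject_table, dtype={"subject_id": str}, float_precision="round_trip"
    )
    visits["subject_id"] = visits["subject_id"].astype(str)

    dup = visits.duplicated(subset=["subject_id", "modality", "visit_month"], keep=False)
    if dup.any():
        row = visits[dup].iloc[0]
        raise CohortError(
            "duplicate visit row: subject "
            f"{row['subject_id']!r}, modality {row['modality']!r}, "
            f"month {row['visit_month']}"
        )

    feature_cols = _feature_columns(registry)
    sequences: dict[str, dict[str, ModalitySequence]] = {}
    for (sid, modality), grp in visits.groupby(["subject_id", "modality"], sort=False):
        if modality not in specs:
            raise CohortError(f"{sid}: modality {modality!r} not in registry")
        spec = specs[modality]
        grp = grp.sort_values("visit_month")
        block = grp[feature_cols].to_numpy(dtype=float)
        used, unused = block[:, : spec.n_features], block[:, spec.n_features :]
        if np.isnan(used).any():
            raise CohortError(
                f"{sid}/{modality}: missing feature values "
                f"(registry expects {spec.n_features} features)"
            )
        if unused.size and not np.isnan(unused).all():
            raise CohortError(
                f"{sid}/{modality}: values beyond the registered "
                f"{spec.n_features} features"
            )
        sequences.setdefault(sid, {})[modality] = ModalitySequence(
            modality, grp["visit_month"].to_numpy(dtype=float), used
        )

    subjects = []
    for row in subjects_df.itertuples(index=False):
        conv = getattr(row, "conversion_month")
        conv = None if pd.isna(conv) else float(conv)
        subjects.append(
            Subject(
                id=str(row.subject_id),
                baseline_group=str(row.baseline_group),
                conversion_month=conv,
                followup_month=float(row.followup_month),
                sequences=sequences.get(str(row.subject_id), {}),
            )
        )
    return Cohort(subjects, list(registry))


def write_cohort(cohort: Cohort, path: str | Path) -> dict[str, Path]:
    """Write ``visits.csv``, ``subjects.csv`` and ``registry.yaml`` under ``path``.

    Feature values are written with full ``repr`` precision so a read/write
    round trip is exact.  Returns the paths written.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    feature_cols = _feature_columns(cohort.registry)

    visit_rows = []
    for s in cohort.subjects:
        for name in sorted(s.sequences):
            seq = s.sequences[name]
            for month, obs in zip(seq.visit_months, seq.observations):
                row: dict[str, object] = {
                    "subject_id": s.id,
                    "modality": name,
                    "visit_month": month,
                }
                for j, col in enumerate(feature_cols):
                    row[col] = obs[j] if j < obs.size else np.nan
                visit_rows.append(row)
    visits = pd.DataFrame(visit_rows, columns=["subject_id", "modality", "visit_month", *feature_cols])

    subjects = pd.DataFrame(
        {
            "subject_id": [s.id for s in cohort.subjects],
            "baseline_group": [s.baseline_group for s in cohort.subjects],
            "conversion_month": [
                np.nan if s.conversion_month is None else s.conversion_month
                for s in cohort.subjects
            ],
            "followup_month": [s.followup_month for s in cohort.subjects],
        }
    )

    paths = {
        "visits": out / "visits.csv",
        "subjects": out / "subjects.csv",
        "registry": out / "registry.yaml",
    }
    # %.17g guarantees bit-exact float round-trips through text
    visits.to_csv(paths["visits"], index=False, float_format="%.17g")
    subjects.to_csv(paths["subjects"], index=False, float_format="%.17g")
    write_registry(cohort.registry, paths["registry"])
    return paths


def load_cohort(path: str | Path) -> Cohort:
    """Read back a directory written by :func:`write_cohort`."""
    p = Path(path)
    registry = read_registry(p / "registry.yaml")
    return read_cohort(p / "visits.csv", p / "subjects.csv", registry)


def read_registry(path: str | Path) -> list[ModalitySpec]:
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    return [
        ModalitySpec(
            name=d["name"],
            n_features=int(d["n_features"]),
            hidden_dim=int(d["hidden_dim"]),
            longitudinal=bool(d["longitudinal"]),
        )
        for d in data
    ]


def write_registry(registry: list[ModalitySpec], path: str | Path) -> None:
    data = [
        {
            "name": spec.name,
            "n_features": spec.n_features,
            "hidden_dim": spec.hidden_dim,
            "longitudinal": spec.longitudinal,
        }
        for spec in registry
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
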