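"""Domain types and deterministic clinical rules for memory-clinic cohorts.

A cohort is a set of patient records, each carrying a clinical diagnosis
(CN/MCI/AD/FTD/VaD/DLB), demographics, and numeric features grouped by
modality: digital cognitive screening (cCOG), neuropsychological tests,
neuropsychiatric scales, functional assessment, automated MRI biomarkers
and CSF biomarkers.  Missing values are first-class citizens throughout.

This module also implements the deterministic biomarker rules used as
ground truth downstream: CSF amyloid positivity (t-tau/Abeta42 ratio
>= 0.46 on the Innotest scale), single-analyte abnormality flags
(Abeta42 < 813 pg/ml, t-tau > 375 pg/ml) and disease-modifying-therapy
(DMT) eligibility (MCI/dementia due to AD, MMSE >= 22, computed
Fazekas < 2.5, amyloid positive).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosisLabel",
    "Modality",
    "Sex",
    "ValidRange",
    "FeatureDef",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "MISSING",
    "INDETERMINATE",
    "Indeterminate",
    "default_schema",
    "is_missing",
    "read_cohort",
    "write_cohort",
    "amyloid_positive",
    "abnormal_flags",
    "eligible_ground_truth",
    "syndrome_of",
    "DEMENTIA_LABELS",
    "AMYLOID_RATIO_CUTOFF",
    "ABETA42_CUTOFF",
    "TTAU_CUTOFF",
]

#: Innotest-scale CSF cutoffs (pg/ml); the ratio cutoff is inclusive
#: (>= 0.46), the single-analyte cutoffs are strict (< 813, > 375).
AMYLOID_RATIO_CUTOFF = 0.46
ABETA42_CUTOFF = 813.0
TTAU_CUTOFF = 375.0

#: Sentinel for absent feature values; NaN compares unequal to itself,
#: so always test with :func:`is_missing`.
MISSING = math.nan


class Indeterminate:
    """Singleton returned by rules whose required inputs are missing.

    Distinct from both ``True`` and ``False`` so callers must handle it
    explicitly; it is falsy to make accidental branching fail loudly in
    tests rather than silently treat it as positive.
    """

    _instance: Optional["Indeterminate"] = None

    def __new__(cls) -> "Indeterminate":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "INDETERMINATE"

    def __bool__(self) -> bool:
        raise TypeError(
            "indeterminate result has no truth value; compare with "
            "'is INDETERMINATE' and handle it explicitly"
        )


INDETERMINATE = Indeterminate()


def is_missing(value: object) -> bool:
    """True for the MISSING sentinel (NaN) or ``None``."""
    if value is None:
        return True
    try:
        return math.isnan(float(value))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return False


class DiagnosisLabel(str, enum.Enum):
    """Clinical diagnosis; CN is the SCD-based cognitively normal group."""

    CN = "CN"
    MCI = "MCI"
    AD = "AD"
    FTD = "FTD"
    VaD = "VaD"
    DLB = "DLB"


DEMENTIA_LABELS = frozenset(
    {DiagnosisLabel.AD, DiagnosisLabel.FTD, DiagnosisLabel.VaD, DiagnosisLabel.DLB}
)


def syndrome_of(diagnosis: DiagnosisLabel) -> str:
    """Collapse an etiological diagnosis to its syndrome stage.

    Returns one of ``"CN"``, ``"MCI"``, ``"DEM"``.
    """
    if diagnosis is DiagnosisLabel.CN:
        return "CN"
    if diagnosis is DiagnosisLabel.MCI:
        return "MCI"
    return "DEM"


class Modality(str, enum.Enum):
    DEMOG = "DEMOG"
    CCOG = "CCOG"
    NP = "NP"
    NEUROPSYCH = "NEUROPSYCH"
    FUNC = "FUNC"
    MRI = "MRI"
    CSF = "CSF"


class Sex(str, enum.Enum):
    female = "F"
    male = "M"


@dataclass(frozen=True)
class ValidRange:
    """Closed numeric interval; ``None`` endpoints are unbounded.

    ``lo_open`` makes the lower bound strict (used for CSF analytes,
    which must be strictly positive).
    """

    lo: Optional[float] = None
    hi: Optional[float] = None
    lo_open: bool = False

    def contains(self, x: float) -> bool:
        if self.lo is not None:
            if self.lo_open:
                if x <= self.lo:
                    return False
            elif x < self.lo:
                return False
        if self.hi is not None and x > self.hi:
            return False
        return True

    def clip(self, x: float) -> float:
        lo = -math.inf if self.lo is None else self.lo
        hi = math.inf if self.hi is None else self.hi
        if self.lo_open and x <= lo:
            # nudge strictly inside; magnitude is irrelevant at CSF scales
            return math.nextafter(lo, math.inf)
        return min(max(x, lo), hi)


@dataclass(frozen=True)
class FeatureDef:
    id: str
    modality: Modality
    valid_range: ValidRange = field(default_factory=ValidRange)
    description: str = ""
    integer_valued: bool = False


def default_schema() -> list[FeatureDef]:
    """The multimodal feature schema of the published memory-clinic work-up.

    Order is the canonical CSV column order.  Demographics (age, sex)
    are record fields, not schema features; education is a feature.
    """
    pos = ValidRange(lo=0.0)
    csf = ValidRange(lo=0.0, lo_open=True)
    return [
        FeatureDef("education", Modality.DEMOG, ValidRange(0, 30), "education, years"),
        FeatureDef("ccog_learning", Modality.CCOG, ValidRange(0, 50), "cCOG word-list learning"),
        FeatureDef("ccog_recall", Modality.CCOG, ValidRange(0, 20), "cCOG word-list delayed recall"),
        FeatureDef("ccog_tmt_a", Modality.CCOG, pos, "cCOG modified trail-making A, s"),
        FeatureDef("ccog_tmt_b", Modality.CCOG, pos, "cCOG modified trail-making B, s"),
        FeatureDef("mmse", Modality.NP, ValidRange(0, 30), "Mini-Mental State Examination", True),
        FeatureDef("memory_learning", Modality.NP, ValidRange(0, 80), "word-list learning total"),
        FeatureDef("memory_recall", Modality.NP, ValidRange(0, 15), "word-list delayed recall"),
        FeatureDef("tmt_a", Modality.NP, pos, "Trail Making Test A, s"),
        FeatureDef("tmt_b", Modality.NP, pos, "Trail Making Test B, s"),
        FeatureDef("fluency", Modality.NP, pos, "animal fluency, words/min"),
        FeatureDef("gds", Modality.NEUROPSYCH, ValidRange(0, 15), "Geriatric Depression Scale", True),
        FeatureDef("npi", Modality.NEUROPSYCH, ValidRange(0, 144), "Neuropsychiatric Inventory total"),
        FeatureDef("dad", Modality.FUNC, ValidRange(0, 100), "Disability Assessment for Dementia"),
        FeatureDef("cmta_left", Modality.MRI, ValidRange(0, 4), "computed medial temporal atrophy, left"),
        FeatureDef("cmta_right", Modality.MRI, ValidRange(0, 4), "computed medial temporal atrophy, right"),
        FeatureDef("cgca", Modality.MRI, ValidRange(0, 3), "computed global cortical atrophy"),
        FeatureDef("cfazekas", Modality.MRI, ValidRange(0, 3), "computed Fazekas grade"),
        FeatureDef("wmh", Modality.MRI, pos, "white-matter hyperintensity volume, ml"),
        FeatureDef("aps", Modality.MRI, ValidRange(), "anterior-posterior atrophy score"),
        FeatureDef("ad_similarity", Modality.MRI, ValidRange(0, 1), "AD similarity index"),
        FeatureDef("abeta42", Modality.CSF, csf, "CSF amyloid beta 1-42, pg/ml"),
        FeatureDef("ttau", Modality.CSF, csf, "CSF total tau, pg/ml"),
        FeatureDef("ptau", Modality.CSF, csf, "CSF phosphorylated tau, pg/ml"),
    ]


class CcogSource(str, enum.Enum):
    measured = "measured"
    simulated = "simulated"


@dataclass
class PatientRecord:
    """One subject: diagnosis, demographics and modality-tagged features."""

    id: str
    diagnosis: DiagnosisLabel
    age: float
    sex: Sex
    features: dict[str, float] = field(default_factory=dict)
    ccog_source: CcogSource = CcogSource.measured

    def get(self, feature_id: str) -> float:
        return self.features.get(feature_id, MISSING)

    def has(self, feature_id: str) -> bool:
        return not is_missing(self.features.get(feature_id, MISSING))

    def copy(self) -> "PatientRecord":
        return replace(self, features=dict(self.features))


class CohortValidationError(ValueError):
    """Raised for any structural or range violation; lists every offence."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n  " + "\n  ".join(self.problems))


@dataclass
class Cohort:
    """A feature schema plus validated patient records."""

    schema: list[FeatureDef]
    records: list[PatientRecord]

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for rec in self.records:
            if rec.id == patient_id:
                return rec
        raise KeyError(patient_id)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Total validation: collects *all* problems before raising."""
        problems: list[str] = []
        by_id = {f.id: f for f in self.schema}
        if len(by_id) != len(self.schema):
            problems.append("duplicate feature ids in schema")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                problems.append(f"duplicate patient id {rec.id!r}")
            seen.add(rec.id)
            for fid, value in rec.features.items():
                if fid not in by_id:
                    problems.append(f"patient {rec.id!r}: unknown feature {fid!r}")
                    continue
                if is_missing(value):
                    continue
                if not by_id[fid].valid_range.contains(float(value)):
                    problems.append(
                        f"patient {rec.id!r}: {fid} = {value!r} outside valid range"
                    )
        if problems:
            raise CohortValidationError(problems)

    # -- convenience --------------------------------------------------------
    def subset(self, predicate) -> "Cohort":
        return Cohort(self.schema, [r for r in self.records if predicate(r)])

    def with_labels(self, labels: Iterable[DiagnosisLabel]) -> "Cohort":
        wanted = set(labels)
        return self.subset(lambda r: r.diagnosis in wanted)

    def feature_ids(self, modalities: Optional[Iterable[Modality]] = None) -> list[str]:
        if modalities is None:
            return [f.id for f in self.schema]
        wanted = set(modalities)
        return [f.id for f in self.schema if f.modality in wanted]

    def to_frame(self) -> pd.DataFrame:
        """Feature matrix (NaN = missing) indexed by patient id, plus
        diagnosis/age/sex columns."""
        rows = []
        for rec in self.records:
            row = {
                "id": rec.id,
                "diagnosis": rec.diagnosis.value,
                "age": rec.age,
                "sex": rec.sex.value,
                "ccog_source": rec.ccog_source.value,
            }
            for f in self.schema:
                row[f.id] = rec.features.get(f.id, MISSING)
            rows.append(row)
        return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def read_cohort(path, schema: Optional[list[FeatureDef]] = None) -> Cohort:
    """Read a cohort CSV (``id,diagnosis,age,sex,<features...>``).

    Empty cells and the literal token ``NA`` become MISSING.  Malformed
    numerics, duplicate ids, unknown diagnosis labels and out-of-range
    values are all reported with row/column context in a single
    :class:`CohortValidationError`.
    """
    schema = schema if schema is not None else default_schema()
    by_id = {f.id: f for f in schema}
    problems: list[str] = []
    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError(["file has no header row"])
        unknown = [c for c in reader.fieldnames if c not in by_id and c not in ("id", "diagnosis", "age", "sex", "ccog_source")]
        if unknown:
            problems.append(f"unknown columns: {unknown}")
        for lineno, row in enumerate(reader, start=2):
            try:
                diagnosis = DiagnosisLabel(row["diagnosis"])
            except (KeyError, ValueError):
                problems.append(f"row {lineno}: unknown diagnosis label {row.get('diagnosis')!r}")
                continue
            try:
                sex = Sex(row["sex"])
            except (KeyError, ValueError):
                problems.append(f"row {lineno}: unknown sex {row.get('sex')!r}")
                continue
            try:
                age = float(row["age"])
            except (KeyError, ValueError):
                problems.append(f"row {lineno}: malformed age {row.get('age')!r}")
                continue
            features: dict[str, float] = {}
            for fid in by_id:
                raw = (row.get(fid) or "").strip()
                if raw in _MISSING_TOKENS:
                    features[fid] = MISSING
                    continue
                try:
                    features[fid] = float(raw)
                except ValueError:
                    problems.append(f"row {lineno}, column {fid!r}: malformed numeric {raw!r}")
            source = CcogSource(row.get("ccog_source") or "measured")
            records.append(PatientRecord(row["id"], diagnosis, age, sex, features, source))
    if problems:
        raise CohortValidationError(problems)
    return Cohort(schema, records)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV in schema column order; MISSING as empty cell."""
    header = ["id", "diagnosis", "age", "sex", "ccog_source"] + [f.id for f in cohort.schema]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in cohort.records:
            row = [rec.id, rec.diagnosis.value, repr(rec.age), rec.sex.value, rec.ccog_source.value]
            for f in cohort.schema:
                v = rec.features.get(f.id, MISSING)
                row.append("" if is_missing(v) else repr(float(v)))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Deterministic biomarker and eligibility rules
# ---------------------------------------------------------------------------


def amyloid_positive(abeta42: float, ttau: float):
    """CSF amyloid positivity: t-tau/Abeta42 ratio >= 0.46 (inclusive).

    Returns INDETERMINATE if either analyte is missing; never silently
    False.
    """
    if is_missing(abeta42) or is_missing(ttau):
        return INDETERMINATE
    if abeta42 <= 0 or ttau <= 0:
        raise ValueError("CSF analyte values must be strictly positive")
    return (ttau / abeta42) >= AMYLOID_RATIO_CUTOFF


def abnormal_flags(abeta42: float, ttau: float):
    """Single-analyte abnormality flags ``(abeta42 < 813, ttau > 375)``.

    Both cutoffs are strict inequalities.  Missing input yields
    INDETERMINATE for the corresponding flag.
    """
    a = INDETERMINATE if is_missing(abeta42) else (abeta42 < ABETA42_CUTOFF)
    t = INDETERMINATE if is_missing(ttau) else (ttau > TTAU_CUTOFF)
    return (a, t)


def eligible_ground_truth(record: PatientRecord):
    """DMT eligibility ground truth, operationalized appropriate-use criteria.

    True iff diagnosis in {MCI, AD} AND amyloid positive AND MMSE >= 22
    AND cFazekas < 2.5 (strict).  "MCI due to AD" is carried by the
    amyloid clause.  INDETERMINATE when amyloid status, MMSE or the
    cFazekas grade is missing, mirroring a complete-data restriction.
    """
    amyloid = amyloid_positive(record.get("abeta42"), record.get("ttau"))
    mmse = record.get("mmse")
    cfazekas = record.get("cfazekas")
    if amyloid is INDETERMINATE or is_missing(mmse) or is_missing(cfazekas):
        return INDETERMINATE
    if record.diagnosis not in (DiagnosisLabel.MCI, DiagnosisLabel.AD):
        return False
    return bool(amyloid) and mmse >= 22 and cfazekas < 2.5
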