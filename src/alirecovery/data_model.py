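"""Core domain types and file readers/writers.

The package exchanges five flat CSV tables (RFC 4180, UTF-8, header row):
``cohort.csv``, ``icd10_catalog.csv``, ``diagnoses.csv``, ``chart_review.csv``
and ``biomarkers.csv``.  Every reader validates the schema and the stated
invariants up front and raises :class:`SchemaError` / :class:`ValidationError`
naming the offending column, row or identifier; readers never silently drop
or coerce data.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("alirecovery")


class SchemaError(ValueError):
    """A file is missing a required column or uses an unknown label."""


class ValidationError(ValueError):
    """A file violates a stated invariant (duplicates, bad values...)."""


# ---------------------------------------------------------------------------
# Component universe
# ---------------------------------------------------------------------------

class BodySystem(str, Enum):
    CARDIOVASCULAR = "cardiovascular"
    METABOLIC = "metabolic"
    INFLAMMATION = "inflammation"


class ComponentId(str, Enum):
    """The ten allostatic load index components, across three body systems."""

    SBP = "SBP"        # systolic blood pressure
    DBP = "DBP"        # diastolic blood pressure
    BMI = "BMI"        # body mass index
    TRIG = "TRIG"      # triglycerides
    CHOL = "CHOL"      # total cholesterol
    CRP = "CRP"        # C-reactive protein
    HBA1C = "HBA1C"    # hemoglobin A1c
    ALB = "ALB"        # serum albumin
    CC = "CC"          # creatinine clearance
    HCST = "HCST"      # homocysteine

    @property
    def body_system(self) -> BodySystem:
        return _BODY_SYSTEMS[self]


_BODY_SYSTEMS: Mapping[ComponentId, BodySystem] = {
    ComponentId.SBP: BodySystem.CARDIOVASCULAR,
    ComponentId.DBP: BodySystem.CARDIOVASCULAR,
    ComponentId.BMI: BodySystem.METABOLIC,
    ComponentId.TRIG: BodySystem.METABOLIC,
    ComponentId.CHOL: BodySystem.METABOLIC,
    ComponentId.CRP: BodySystem.INFLAMMATION,
    ComponentId.HBA1C: BodySystem.INFLAMMATION,
    ComponentId.ALB: BodySystem.INFLAMMATION,
    ComponentId.CC: BodySystem.INFLAMMATION,
    ComponentId.HCST: BodySystem.INFLAMMATION,
}


class Status(str, Enum):
    """Four-way classification of a patient-component data point."""

    UNHEALTHY = "UNHEALTHY"
    HEALTHY = "HEALTHY"
    MISSING = "MISSING"
    PROTOCOL_ERROR = "PROTOCOL_ERROR"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patient:
    patient_id: str
    age: float
    sex: Sex
    race: str = ""
    ethnicity: str = ""
    engaged: bool = False


@dataclass(frozen=True)
class Icd10Entry:
    code: str
    description: str


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    code: str
    date: _dt.date
    resolved: bool = True  # False when the code is absent from the catalog


@dataclass(frozen=True)
class ComponentRecord:
    patient_id: str
    component: ComponentId
    value: float | None
    status: Status
    # Preserved pre-reclassification label, for audit (protocol errors).
    original_status: Status | None = None


@dataclass(frozen=True)
class ChartReviewRecord:
    patient_id: str
    component: ComponentId
    reviewed_status: Status


class ICD10Catalog:
    """Exact-match code -> description dictionary."""

    def __init__(self, entries: Iterable[Icd10Entry] = ()):
        self._entries: dict[str, Icd10Entry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: Icd10Entry) -> None:
        if not entry.code:
            raise ValidationError("ICD-10 code must be non-empty")
        if not entry.description:
            raise ValidationError(f"empty description for code {entry.code!r}")
        existing = self._entries.get(entry.code)
        if existing is not None:
            if existing.description != entry.description:
                raise ValidationError(
                    f"duplicate code {entry.code!r} with conflicting descriptions"
                )
            logger.warning("duplicate code %s with identical description; kept once", entry.code)
            return
        self._entries[entry.code] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, code: str) -> Icd10Entry | None:
        return self._entries.get(code)

    def description(self, code: str) -> str:
        return self._entries[code].description

    @property
    def codes(self) -> set[str]:
        return set(self._entries)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"unparseable boolean value {x!r}")


def read_cohort(path: str | Path) -> list[Patient]:
    """Read ``cohort.csv`` (patient_id, age, sex, [race, ethnicity], engaged)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["patient_id", "age", "sex", "engaged"], path)
    dup = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate patient_id values: {dup}")
    patients = []
    for _, row in df.iterrows():
        sex_raw = row["sex"].strip().lower()
        try:
            sex = Sex(sex_raw)
        except ValueError:
            raise ValidationError(
                f"{path}: patient {row['patient_id']!r} has sex {row['sex']!r}; "
                f"expected one of {[s.value for s in Sex]}"
            ) from None
        patients.append(
            Patient(
                patient_id=row["patient_id"],
                age=float(row["age"]),
                sex=sex,
                race=row.get("race", "").strip(),
                ethnicity=row.get("ethnicity", "").strip(),
                engaged=_parse_bool(row["engaged"]),
            )
        )
    return patients


def write_cohort(patients: Iterable[Patient], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex.value,
                "race": p.race,
                "ethnicity": p.ethnicity,
                "engaged": p.engaged,
            }
            for p in patients
        ],
        columns=["patient_id", "age", "sex", "race", "ethnicity", "engaged"],
    )
    df.to_csv(path, index=False)


def read_icd10_catalog(path: str | Path) -> ICD10Catalog:
    """Read ``icd10_catalog.csv`` (code, description); duplicates must agree."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["code", "description"], path)
    catalog = ICD10Catalog()
    for _, row in df.iterrows():
        catalog.add(Icd10Entry(code=row["code"], description=row["description"]))
    return catalog


def write_icd10_catalog(catalog: ICD10Catalog, path: str | Path) -> None:
    df = pd.DataFrame(
        [{"code": e.code, "description": e.description} for e in catalog],
        columns=["code", "description"],
    )
    df.to_csv(path, index=False)


def read_diagnoses(path: str | Path, catalog: ICD10Catalog | None = None) -> list[DiagnosisRecord]:
    """Read ``diagnoses.csv`` (patient_id, code, date).

    Codes absent from ``catalog`` are retained but flagged ``resolved=False``
    (they can never match a roadmap term, but per-patient code counts should
    reflect the raw file).  Unparseable dates raise with the line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["patient_id", "code", "date"], path)
    records = []
    n_unresolved = 0
    for i, row in df.iterrows():
        try:
            date = _dt.date.fromisoformat(row["date"])
        except ValueError:
            raise ValidationError(
                f"{path}: line {i + 2}: unparseable date {row['date']!r} (expected YYYY-MM-DD)"
            ) from None
        resolved = catalog is None or row["code"] in catalog
        if not resolved:
            n_unresolved += 1
        records.append(
            DiagnosisRecord(
                patient_id=row["patient_id"], code=row["code"], date=date, resolved=resolved
            )
        )
    if n_unresolved:
        logger.warning("%d diagnosis records carry codes absent from the catalog", n_unresolved)
    return records


def write_diagnoses(records: Iterable[DiagnosisRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"patient_id": r.patient_id, "code": r.code, "date": r.date.isoformat()}
            for r in records
        ],
        columns=["patient_id", "code", "date"],
    )
    df.to_csv(path, index=False)


def unique_code_counts(records: Iterable[DiagnosisRecord]) -> dict[str, int]:
    """Number of distinct ICD-10 codes carried by each patient."""
    seen: dict[str, set[str]] = {}
    for r in records:
        seen.setdefault(r.patient_id, set()).add(r.code)
    return {pid: len(codes) for pid, codes in seen.items()}


def read_biomarkers(path: str | Path) -> list[ComponentRecord]:
    """Read ``biomarkers.csv`` (patient_id, component, value; blank = missing).

    Statuses are not stored in this file: records come back with
    ``Status.MISSING`` when the value is blank and are otherwise discretized
    downstream by the phenotype module (status placeholder ``HEALTHY``
    is *not* assigned here -- the value is carried through as-is with a
    MISSING/nonmissing split only).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["patient_id", "component", "value"], path)
    out = []
    for i, row in df.iterrows():
        comp = _parse_component(row["component"], path, i)
        raw = row["value"].strip()
        value = float(raw) if raw else None
        status = Status.MISSING if value is None else Status.HEALTHY  # provisional
        out.append(ComponentRecord(row["patient_id"], comp, value, status))
    return out


def write_biomarkers(records: Iterable[ComponentRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "component": r.component.value,
                "value": "" if r.value is None else repr(r.value),
            }
            for r in records
        ],
        columns=["patient_id", "component", "value"],
    )
    df.to_csv(path, index=False)


def _parse_component(label: str, path: Path, i: int) -> ComponentId:
    try:
        return ComponentId(label.strip().upper())
    except ValueError:
        raise SchemaError(
            f"{path}: line {i + 2}: unknown component label {label!r}; "
            f"expected one of {[c.value for c in ComponentId]}"
        ) from None


def read_chart_review(path: str | Path) -> list[ChartReviewRecord]:
    """Read ``chart_review.csv`` (patient_id, component, reviewed_status)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["patient_id", "component", "reviewed_status"], path)
    seen: set[tuple[str, ComponentId]] = set()
    out = []
    for i, row in df.iterrows():
        comp = _parse_component(row["component"], path, i)
        key = (row["patient_id"], comp)
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate chart-review record for patient "
                f"{row['patient_id']!r}, component {comp.value}"
            )
        seen.add(key)
        try:
            status = Status(row["reviewed_status"].strip().upper())
        except ValueError:
            raise ValidationError(
                f"{path}: line {i + 2}: unknown status {row['reviewed_status']!r}"
            ) from None
        out.append(ChartReviewRecord(row["patient_id"], comp, status))
    return out


def write_chart_review(records: Iterable[ChartReviewRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "component": r.component.value,
                "reviewed_status": r.reviewed_status.value,
            }
            for r in records
        ],
        columns=["patient_id", "component", "reviewed_status"],
    )
    df.to_csv(path, index=False)
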