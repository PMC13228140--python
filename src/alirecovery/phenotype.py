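"""Discretization at clinical thresholds and the allostatic load index (ALI).

The ALI is the proportion of a patient's ten biomarkers in the unhealthy
range.  Thresholds ship as editable YAML data (``data/thresholds.yaml``), so
alternative ALI calculations need no code change.  The denominator is
configurable: ``nonmissing`` (default) divides the unhealthy count by the
number of non-missing components; ``all10`` divides by 10 regardless.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Literal, Mapping

import yaml

from .data_model import ComponentId, ComponentRecord, Sex, Status

DenominatorMode = Literal["nonmissing", "all10"]

_DIRECTIONS = {"greater", "greater_equal", "less", "less_equal"}


@dataclass(frozen=True)
class ThresholdRule:
    component: ComponentId
    direction: str
    cutoff: float | Mapping[Sex, float]  # sex-keyed pair for creatinine clearance
    units: str = ""

    def cutoff_for(self, sex: Sex | None) -> float:
        if isinstance(self.cutoff, Mapping):
            if sex is None:
                raise ValueError(
                    f"{self.component.value}: sex-specific threshold requires a known sex"
                )
            return self.cutoff[sex]
        return float(self.cutoff)

    def is_unhealthy(self, value: float, sex: Sex | None = None) -> bool:
        cut = self.cutoff_for(sex)
        if self.direction == "greater":
            return value > cut
        if self.direction == "greater_equal":
            return value >= cut
        if self.direction == "less":
            return value < cut
        if self.direction == "less_equal":
            return value <= cut
        raise ValueError(f"unknown direction {self.direction!r}")


def load_thresholds(path: str | Path | None = None) -> dict[ComponentId, ThresholdRule]:
    """Load the threshold table (packaged default, or a caller-supplied YAML)."""
    if path is None:
        text = files("alirecovery").joinpath("data/thresholds.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    rules: dict[ComponentId, ThresholdRule] = {}
    for key, spec in raw.items():
        comp = ComponentId(key)
        direction = spec["direction"]
        if direction not in _DIRECTIONS:
            raise ValueError(f"{key}: unknown direction {direction!r}")
        cutoff = spec["cutoff"]
        if isinstance(cutoff, Mapping):
            cutoff = {Sex(k): float(v) for k, v in cutoff.items()}
        rules[comp] = ThresholdRule(comp, direction, cutoff, spec.get("units", ""))
    missing = set(ComponentId) - set(rules)
    if missing:
        raise ValueError(f"threshold table lacks rules for {sorted(c.value for c in missing)}")
    return rules


_DEFAULT_RULES: dict[ComponentId, ThresholdRule] | None = None


def default_thresholds() -> dict[ComponentId, ThresholdRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_thresholds()
    return _DEFAULT_RULES


def discretize(
    component: ComponentId,
    value: float | None,
    sex: Sex | None = None,
    rules: Mapping[ComponentId, ThresholdRule] | None = None,
) -> Status:
    """Pure function: numeric value -> UNHEALTHY / HEALTHY / MISSING.

    Boundary semantics follow the printed inequality strictness exactly
    (e.g. systolic pressure 140 is HEALTHY under ">140", triglycerides 150
    UNHEALTHY under ">=150").  Creatinine clearance without a known sex is
    an error: the threshold is undeterminable.
    """
    if value is None:
        return Status.MISSING
    rule = (rules or default_thresholds())[component]
    return Status.UNHEALTHY if rule.is_unhealthy(value, sex) else Status.HEALTHY


def discretize_records(
    records: Iterable[ComponentRecord],
    sex_by_patient: Mapping[str, Sex],
    rules: Mapping[ComponentId, ThresholdRule] | None = None,
) -> list[ComponentRecord]:
    """Discretize a batch of biomarker records using per-patient sex."""
    out = []
    for r in records:
        status = discretize(r.component, r.value, sex_by_patient.get(r.patient_id), rules)
        out.append(ComponentRecord(r.patient_id, r.component, r.value, status))
    return out


@dataclass(frozen=True)
class AliScore:
    patient_id: str
    n_unhealthy: int
    n_nonmissing: int
    value: float | None  # None when undefined (all components missing, nonmissing mode)
    denominator_mode: DenominatorMode = "nonmissing"

    @property
    def defined(self) -> bool:
        return self.value is not None


def compute_ali(
    records: Iterable[ComponentRecord], mode: DenominatorMode = "nonmissing"
) -> AliScore:
    """ALI for one patient from exactly one record per component.

    nonmissing mode: unhealthy / non-missing (undefined if all 10 missing);
    all10 mode: unhealthy / 10.
    """
    recs = list(records)
    comps = [r.component for r in recs]
    if len(recs) != len(ComponentId) or set(comps) != set(ComponentId):
        raise ValueError("compute_ali needs exactly one record per component")
    bad = [r for r in recs if r.status not in (Status.UNHEALTHY, Status.HEALTHY, Status.MISSING)]
    if bad:
        raise ValueError(f"unexpected status {bad[0].status} (reclassify protocol errors first)")
    pid = recs[0].patient_id
    n_unhealthy = sum(r.status is Status.UNHEALTHY for r in recs)
    n_nonmissing = sum(r.status is not Status.MISSING for r in recs)
    if mode == "nonmissing":
        value = None if n_nonmissing == 0 else n_unhealthy / n_nonmissing
    elif mode == "all10":
        value = n_unhealthy / len(ComponentId)
    else:
        raise ValueError(f"unknown denominator mode {mode!r}")
    return AliScore(pid, n_unhealthy, n_nonmissing, value, mode)


def compute_ali_table(
    records: Iterable[ComponentRecord], mode: DenominatorMode = "nonmissing"
) -> dict[str, AliScore]:
    """Per-patient ALI scores for a flat record collection."""
    by_patient: dict[str, list[ComponentRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return {pid: compute_ali(recs, mode) for pid, recs in by_patient.items()}
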