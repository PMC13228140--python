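"""The missing-data recovery algorithm.

A MISSING patient-component data point is flipped to UNHEALTHY when the
patient carries at least one diagnosis whose ICD-10 code is in that
component's matched-code set.  Recovery is strictly one-sided: a missing
point can only become unhealthy, never healthy (auxiliary diagnoses are
one-sided evidence of poor health), and non-missing points are immutable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .data_model import (
    ChartReviewRecord,
    ComponentId,
    ComponentRecord,
    DiagnosisRecord,
    Status,
)
from .matching import MatchUniverse


@dataclass(frozen=True)
class RecoveryResult:
    patient_id: str
    component: ComponentId
    pre_status: Status
    post_status: Status
    # every (code, term) pair justifying the flip; empty iff no flip
    evidence: tuple[tuple[str, str], ...] = ()

    @property
    def recovered(self) -> bool:
        return self.pre_status is Status.MISSING and self.post_status is Status.UNHEALTHY


def reclassify_protocol_errors(
    records: Iterable[ChartReviewRecord | ComponentRecord],
) -> list[ComponentRecord]:
    """PROTOCOL_ERROR -> MISSING, preserving the original label for audit.

    Chart reviewers occasionally recorded a value from outside the study
    period instead of applying the roadmap; those points are returned to
    missing for comparisons (the algorithm may still recover them).
    Idempotent; everything else passes through unchanged.
    """
    out = []
    for r in records:
        status = r.reviewed_status if isinstance(r, ChartReviewRecord) else r.status
        value = None if isinstance(r, ChartReviewRecord) else r.value
        original = getattr(r, "original_status", None)
        if status is Status.PROTOCOL_ERROR:
            out.append(
                ComponentRecord(r.patient_id, r.component, None, Status.MISSING,
                                original_status=Status.PROTOCOL_ERROR)
            )
        else:
            out.append(ComponentRecord(r.patient_id, r.component, value, status,
                                       original_status=original))
    return out


def recover(
    records: Iterable[ComponentRecord],
    diagnoses: Iterable[DiagnosisRecord],
    universe: MatchUniverse,
) -> list[RecoveryResult]:
    """Apply the roadmap-driven recovery algorithm to every data point.

    Matching is existence-based: any diagnosis within the supplied records
    counts, with no lookback restriction (a found code marks the component
    unhealthy for the whole study period).  Deterministic and idempotent.
    """
    codes_by_patient: dict[str, set[str]] = {}
    for d in diagnoses:
        codes_by_patient.setdefault(d.patient_id, set()).add(d.code)

    results = []
    for r in records:
        if r.status not in (Status.UNHEALTHY, Status.HEALTHY, Status.MISSING):
            raise ValueError(
                f"{r.patient_id}/{r.component.value}: status {r.status.value}; "
                "reclassify protocol errors before recovery"
            )
        if r.status is not Status.MISSING:
            results.append(RecoveryResult(r.patient_id, r.component, r.status, r.status))
            continue
        carried = codes_by_patient.get(r.patient_id, set())
        matched = carried & universe.component_codes(r.component)
        if matched:
            evidence = tuple(
                sorted(
                    (code, term)
                    for code in matched
                    for term in universe.evidence[r.component].get(code, {""})
                )
            )
            results.append(
                RecoveryResult(r.patient_id, r.component, Status.MISSING,
                               Status.UNHEALTHY, evidence)
            )
        else:
            results.append(RecoveryResult(r.patient_id, r.component,
                                          Status.MISSING, Status.MISSING))
    return results


def apply_results(results: Iterable[RecoveryResult]) -> list[ComponentRecord]:
    """Post-recovery statuses as ComponentRecords (no numeric value is imputed)."""
    return [
        ComponentRecord(r.patient_id, r.component, None, r.post_status) for r in results
    ]


def chart_recovery_results(
    ehr_records: Iterable[ComponentRecord],
    chart_records: Iterable[ComponentRecord],
) -> list[RecoveryResult]:
    """Express chart-review recoveries through the RecoveryResult interface.

    For every EHR data point, the pre status is the extracted-EHR status and
    the post status reflects the chart review: a MISSING point recovered as
    UNHEALTHY by the reviewer is a recovery; everything else passes through.
    Protocol errors must already be reclassified to MISSING.  This puts the
    chart review on the same footing as the algorithm for disagreement
    accounting.
    """
    chart_status = {(r.patient_id, r.component): r.status for r in chart_records}
    results = []
    for r in ehr_records:
        post = r.status
        if r.status is Status.MISSING:
            cs = chart_status.get((r.patient_id, r.component), Status.MISSING)
            post = Status.UNHEALTHY if cs is Status.UNHEALTHY else Status.MISSING
        results.append(RecoveryResult(r.patient_id, r.component, r.status, post))
    return results


def recovery_counts(
    results: Iterable[RecoveryResult],
) -> tuple[int, int, float | None]:
    """(n_missing_pre, n_recovered, percent recovered).

    Percent is 100 * recovered / missing-pre; None when nothing was missing.
    """
    results = list(results)
    n_missing_pre = sum(r.pre_status is Status.MISSING for r in results)
    n_recovered = sum(r.recovered for r in results)
    pct = None if n_missing_pre == 0 else 100.0 * n_recovered / n_missing_pre
    return n_missing_pre, n_recovered, pct


def write_recovery_results(results: Iterable[RecoveryResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "component": r.component.value,
                "pre_status": r.pre_status.value,
                "post_status": r.post_status.value,
                "evidence_codes": ";".join(sorted({c for c, _ in r.evidence})),
            }
            for r in results
        ],
        columns=["patient_id", "component", "pre_status", "post_status", "evidence_codes"],
    )
    df.to_csv(path, index=False)
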