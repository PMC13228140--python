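"""Comparison statistics: status-flow accounting, missingness summaries,
chart-vs-algorithm disagreements, ALI distribution shifts, and the
engagement logistic regression.

Quantile convention: medians and quartiles use linear interpolation
(numpy's default), the convention most common in statistical software, so
interquartile-range assertions are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import ComponentId, ComponentRecord, Patient, Status, logger
from .phenotype import AliScore
from .recovery import RecoveryResult


class IntegrityError(RuntimeError):
    """A status transition violates the one-sided recovery rule."""


# ---------------------------------------------------------------------------
# Status-flow accounting
# ---------------------------------------------------------------------------

@dataclass
class FlowTable:
    """Counts of data points by status, before and after one comparison source."""

    source: str
    pre_counts: dict[Status, int]
    post_counts: dict[Status, int]
    transitions: dict[tuple[Status, Status], int]
    n_points: int

    @property
    def n_missing_pre(self) -> int:
        return self.pre_counts.get(Status.MISSING, 0)

    @property
    def n_recovered(self) -> int:
        return self.transitions.get((Status.MISSING, Status.UNHEALTHY), 0)


def build_flow(
    ehr: Iterable[ComponentRecord],
    other: Iterable[ComponentRecord],
    source: str = "algorithm",
    enforce_one_sided: bool = True,
) -> FlowTable:
    """Tabulate status transitions between the extracted-EHR baseline and a
    comparison source over the same (patient, component) universe.

    For algorithm sources only MISSING -> UNHEALTHY transitions are legal;
    anything else raises :class:`IntegrityError` (an assertion, not a silent
    correction).  Totals are conserved: each column sums to the number of
    data points.
    """
    pre = {(r.patient_id, r.component): r.status for r in ehr}
    post = {(r.patient_id, r.component): r.status for r in other}
    if set(pre) != set(post):
        raise IntegrityError("pre and post sources cover different (patient, component) sets")

    pre_counts = {s: 0 for s in Status}
    post_counts = {s: 0 for s in Status}
    transitions: dict[tuple[Status, Status], int] = {}
    for key, s_pre in pre.items():
        s_post = post[key]
        pre_counts[s_pre] += 1
        post_counts[s_post] += 1
        transitions[(s_pre, s_post)] = transitions.get((s_pre, s_post), 0) + 1
        if enforce_one_sided and s_pre is not s_post:
            if not (s_pre is Status.MISSING and s_post is Status.UNHEALTHY):
                raise IntegrityError(
                    f"illegal transition {s_pre.value} -> {s_post.value} for "
                    f"{key[0]}/{key[1].value} in source {source!r}"
                )
    return FlowTable(source, pre_counts, post_counts, transitions, n_points=len(pre))


# ---------------------------------------------------------------------------
# Missingness summaries
# ---------------------------------------------------------------------------

@dataclass
class MissingnessSummary:
    n_patients: int
    per_patient_nonmissing: dict[str, int]
    median_nonmissing: float
    q1_nonmissing: float
    q3_nonmissing: float
    per_component_missing: dict[ComponentId, int]


def missingness_summary(records: Iterable[ComponentRecord]) -> MissingnessSummary:
    """Per-patient non-missing counts (median, quartiles) and per-component
    missing counts."""
    nonmissing: dict[str, int] = {}
    per_comp = {c: 0 for c in ComponentId}
    for r in records:
        nonmissing.setdefault(r.patient_id, 0)
        if r.status is Status.MISSING:
            per_comp[r.component] += 1
        else:
            nonmissing[r.patient_id] += 1
    counts = np.array(list(nonmissing.values()), dtype=float)
    if counts.size == 0:
        med = q1 = q3 = float("nan")
    else:
        q1, med, q3 = np.percentile(counts, [25, 50, 75])
    return MissingnessSummary(
        n_patients=len(nonmissing),
        per_patient_nonmissing=nonmissing,
        median_nonmissing=float(med),
        q1_nonmissing=float(q1),
        q3_nonmissing=float(q3),
        per_component_missing=per_comp,
    )


# ---------------------------------------------------------------------------
# Disagreements
# ---------------------------------------------------------------------------

@dataclass
class DisagreementReport:
    """Per-component partition of recovered points into chart-only,
    algorithm-only, and agreement sets."""

    chart_only: dict[ComponentId, int]
    algorithm_only: dict[ComponentId, int]
    agreements: dict[ComponentId, int]

    def totals(self) -> tuple[int, int, int]:
        return (
            sum(self.chart_only.values()),
            sum(self.algorithm_only.values()),
            sum(self.agreements.values()),
        )


def disagreements(
    chart: Iterable[RecoveryResult], algo: Iterable[RecoveryResult]
) -> DisagreementReport:
    """Two disagreement types: the chart review recovered a point the
    algorithm did not, and vice versa; agreements are points both recovered."""
    chart_rec = {(r.patient_id, r.component) for r in chart if r.recovered}
    algo_rec = {(r.patient_id, r.component) for r in algo if r.recovered}
    chart_only = {c: 0 for c in ComponentId}
    algo_only = {c: 0 for c in ComponentId}
    agree = {c: 0 for c in ComponentId}
    for _, comp in chart_rec - algo_rec:
        chart_only[comp] += 1
    for _, comp in algo_rec - chart_rec:
        algo_only[comp] += 1
    for _, comp in chart_rec & algo_rec:
        agree[comp] += 1
    return DisagreementReport(chart_only, algo_only, agree)


# ---------------------------------------------------------------------------
# Engagement regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionSummary:
    coef_ali: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int
    n_excluded: int = 0
    separation_flag: bool = False
    degenerate_flag: bool = False  # constant ALI: zero-information design


def engagement_model(
    patients: Sequence[Patient], ali: Mapping[str, AliScore], alpha: float = 0.05
) -> RegressionSummary:
    """Maximum-likelihood logistic regression of care engagement on ALI,
    with Wald confidence intervals.

    Patients with an undefined ALI (all ten components missing under the
    nonmissing denominator) are excluded, with the count reported.  Complete
    separation is flagged and the CI reported as unbounded; a constant ALI
    is flagged as a degenerate (zero-information) design.
    """
    rows = []
    n_excluded = 0
    for p in patients:
        score = ali.get(p.patient_id)
        if score is None or not score.defined:
            n_excluded += 1
            continue
        rows.append((score.value, 1.0 if p.engaged else 0.0))
    if not rows:
        raise ValueError("no patients with a defined ALI")
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])

    if np.ptp(x) == 0.0:
        logger.warning("ALI constant across patients: coefficient not identifiable")
        return RegressionSummary(
            coef_ali=float("nan"), intercept=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"),
            n=len(rows), n_excluded=n_excluded, degenerate_flag=True,
        )

    X = sm.add_constant(x)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            separation = True
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
    params = np.asarray(fit.params)
    if not separation:
        try:
            ci = np.asarray(fit.conf_int(alpha=alpha))
            se = np.asarray(fit.bse)
            if not np.all(np.isfinite(se)) or np.any(se > 1e3):
                separation = True
        except Exception:
            separation = True
    if separation:
        ci_low, ci_high = -np.inf, np.inf
        logger.warning("possible complete separation: CI reported as unbounded")
    else:
        ci_low, ci_high = float(ci[1, 0]), float(ci[1, 1])
    return RegressionSummary(
        coef_ali=float(params[1]),
        intercept=float(params[0]),
        ci_low=ci_low,
        ci_high=ci_high,
        n=len(rows),
        n_excluded=n_excluded,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def ali_distribution(ali: Mapping[str, AliScore]) -> dict[str, float]:
    vals = np.array([s.value for s in ali.values() if s.defined])
    if vals.size == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"n": int(vals.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def write_evaluation_report(
    path: str | Path,
    flows: Mapping[str, FlowTable],
    missingness: Mapping[str, MissingnessSummary],
    disagreement: DisagreementReport | None,
    ali_pre: Mapping[str, AliScore],
    ali_post: Mapping[str, AliScore],
    regression: RegressionSummary | None = None,
) -> dict:
    """Assemble and write the full machine-readable evaluation report."""
    report: dict = {
        "flows": {
            name: {
                "n_points": f.n_points,
                "pre": {s.value: c for s, c in f.pre_counts.items()},
                "post": {s.value: c for s, c in f.post_counts.items()},
                "n_missing_pre": f.n_missing_pre,
                "n_recovered": f.n_recovered,
                "pct_recovered": (
                    None if f.n_missing_pre == 0
                    else 100.0 * f.n_recovered / f.n_missing_pre
                ),
            }
            for name, f in flows.items()
        },
        "missingness": {
            name: {
                "n_patients": m.n_patients,
                "median_nonmissing": m.median_nonmissing,
                "iqr_nonmissing": [m.q1_nonmissing, m.q3_nonmissing],
                "per_component_missing": {
                    c.value: n for c, n in m.per_component_missing.items()
                },
            }
            for name, m in missingness.items()
        },
        "ali": {"pre": ali_distribution(ali_pre), "post": ali_distribution(ali_post)},
    }
    if disagreement is not None:
        report["disagreements"] = {
            "chart_only": {c.value: n for c, n in disagreement.chart_only.items()},
            "algorithm_only": {c.value: n for c, n in disagreement.algorithm_only.items()},
            "agreements": {c.value: n for c, n in disagreement.agreements.items()},
        }
    if regression is not None:
        report["engagement_regression"] = {
            "coef_ali": regression.coef_ali,
            "intercept": regression.intercept,
            "ci95": [regression.ci_low, regression.ci_high],
            "n": regression.n,
            "n_excluded": regression.n_excluded,
            "separation_flag": regression.separation_flag,
            "degenerate_flag": regression.degenerate_flag,
        }
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def export_scatter(
    ali_pre: Mapping[str, AliScore], ali_post: Mapping[str, AliScore], path: str | Path
) -> None:
    """Per-patient (ali_pre, ali_post) pairs, no smoothing."""
    rows = [
        {
            "patient_id": pid,
            "ali_pre": ali_pre[pid].value,
            "ali_post": ali_post[pid].value,
        }
        for pid in sorted(ali_pre)
        if pid in ali_post
    ]
    pd.DataFrame(rows, columns=["patient_id", "ali_pre", "ali_post"]).to_csv(path, index=False)
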