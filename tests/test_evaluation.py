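"""Flow accounting, missingness summaries, disagreements, engagement model."""

import numpy as np
import pytest

from alirecovery import (
    ComponentId,
    ComponentRecord,
    IntegrityError,
    Patient,
    RecoveryResult,
    Sex,
    Status,
    build_flow,
    disagreements,
    engagement_model,
    missingness_summary,
)
from alirecovery.phenotype import AliScore


def _rec(pid, comp, status):
    value = None if status is Status.MISSING else 1.0
    return ComponentRecord(pid, comp, value, status)


class TestBuildFlow:
    def test_illegal_transition_raises(self):
        ehr = [_rec("A", ComponentId.SBP, Status.HEALTHY)]
        other = [_rec("A", ComponentId.SBP, Status.UNHEALTHY)]
        with pytest.raises(IntegrityError, match="HEALTHY -> UNHEALTHY"):
            build_flow(ehr, other)

    def test_identical_inputs_zero_transitions(self):
        recs = [_rec("A", c, Status.HEALTHY) for c in ComponentId]
        flow = build_flow(recs, recs)
        assert flow.n_recovered == 0
        assert flow.transitions == {(Status.HEALTHY, Status.HEALTHY): 10}

    def test_universe_mismatch_raises(self):
        ehr = [_rec("A", ComponentId.SBP, Status.HEALTHY)]
        other = [_rec("B", ComponentId.SBP, Status.HEALTHY)]
        with pytest.raises(IntegrityError, match="different"):
            build_flow(ehr, other)

    def test_totals_conserved_on_random_instance(self):
        rng = np.random.default_rng(5)
        ehr, other = [], []
        n = 40
        for i in range(n):
            pid = f"P{i}"
            for comp in ComponentId:
                pre = [Status.UNHEALTHY, Status.HEALTHY, Status.MISSING][
                    int(rng.integers(0, 3))
                ]
                post = pre
                if pre is Status.MISSING and rng.random() < 0.3:
                    post = Status.UNHEALTHY
                ehr.append(_rec(pid, comp, pre))
                other.append(_rec(pid, comp, post))
        flow = build_flow(ehr, other)
        assert sum(flow.pre_counts.values()) == 10 * n
        assert sum(flow.post_counts.values()) == 10 * n
        # counting oracle
        expected_recovered = sum(
            1 for a, b in zip(ehr, other)
            if a.status is Status.MISSING and b.status is Status.UNHEALTHY
        )
        assert flow.n_recovered == expected_recovered


class TestMissingnessSummary:
    def test_complete_data(self):
        recs = [_rec(f"P{i}", c, Status.HEALTHY) for i in range(4) for c in ComponentId]
        s = missingness_summary(recs)
        assert s.median_nonmissing == 10
        assert all(v == 0 for v in s.per_component_missing.values())

    def test_single_patient_four_missing(self):
        statuses = [Status.MISSING] * 4 + [Status.HEALTHY] * 6
        recs = [_rec("A", c, st) for c, st in zip(ComponentId, statuses)]
        assert missingness_summary(recs).median_nonmissing == 6

    def test_per_component_counts_match_generator_rates(self, small_study):
        from alirecovery import discretize_records

        sex = {p.patient_id: p.sex for p in small_study["patients"]}
        ehr = discretize_records(small_study["biomarkers"], sex)
        s = missingness_summary(ehr)
        n = len(small_study["patients"])
        for comp in ComponentId:
            rate = 1.0 - small_study["config"].measurement_prob[comp]
            se = np.sqrt(max(rate * (1 - rate), 1e-9) * n)
            assert abs(s.per_component_missing[comp] - n * rate) <= 4 * se + 1


class TestDisagreements:
    def _result(self, pid, comp, recovered):
        post = Status.UNHEALTHY if recovered else Status.MISSING
        return RecoveryResult(pid, comp, Status.MISSING, post)

    def test_cross_disagreement(self):
        chart = [self._result("A", ComponentId.CRP, True),
                 self._result("B", ComponentId.CRP, False)]
        algo = [self._result("A", ComponentId.CRP, False),
                self._result("B", ComponentId.CRP, True)]
        rep = disagreements(chart, algo)
        assert rep.chart_only[ComponentId.CRP] == 1
        assert rep.algorithm_only[ComponentId.CRP] == 1
        assert rep.agreements[ComponentId.CRP] == 0

    def test_identical_recoveries_no_disagreement(self):
        results = [self._result("A", c, True) for c in ComponentId]
        rep = disagreements(results, results)
        assert rep.totals() == (0, 0, 10)

    def test_equals_set_difference_oracle(self):
        rng = np.random.default_rng(3)
        chart, algo = [], []
        for i in range(200):
            pid, comp = f"P{i}", list(ComponentId)[i % 10]
            chart.append(self._result(pid, comp, rng.random() < 0.3))
            algo.append(self._result(pid, comp, rng.random() < 0.3))
        rep = disagreements(chart, algo)
        c = {(r.patient_id, r.component) for r in chart if r.recovered}
        a = {(r.patient_id, r.component) for r in algo if r.recovered}
        assert rep.totals() == (len(c - a), len(a - c), len(c & a))


def _patients_with_ali(n, beta0, beta1, seed):
    rng = np.random.default_rng(seed)
    ali_vals = rng.integers(0, 11, size=n) / 10.0
    patients, ali = [], {}
    for i, v in enumerate(ali_vals):
        p_eng = 1 / (1 + np.exp(-(beta0 + beta1 * v)))
        pid = f"P{i}"
        patients.append(Patient(pid, 40.0, Sex.FEMALE, engaged=rng.random() < p_eng))
        ali[pid] = AliScore(pid, int(v * 10), 10, float(v))
    return patients, ali


class TestEngagementModel:
    def test_constant_ali_flagged_degenerate(self):
        patients = [Patient(f"P{i}", 40.0, Sex.MALE, engaged=i % 2 == 0) for i in range(20)]
        ali = {p.patient_id: AliScore(p.patient_id, 3, 10, 0.3) for p in patients}
        summary = engagement_model(patients, ali)
        assert summary.degenerate_flag

    def test_undefined_ali_excluded_and_counted(self):
        patients, ali = _patients_with_ali(100, -1.0, 1.5, 0)
        ali["P0"] = AliScore("P0", 0, 0, None)
        summary = engagement_model(patients, ali)
        assert summary.n == 99 and summary.n_excluded == 1

    def test_parameter_recovery_at_n5000(self):
        beta1 = 1.5
        patients, ali = _patients_with_ali(5000, -1.25, beta1, 42)
        summary = engagement_model(patients, ali)
        se = (summary.ci_high - summary.ci_low) / (2 * 1.96)
        assert abs(summary.coef_ali - beta1) < 3 * se
        assert summary.ci_low < summary.coef_ali < summary.ci_high

    def test_doubling_observations_leaves_estimate_unchanged(self):
        patients, ali = _patients_with_ali(400, -1.0, 2.0, 1)
        single = engagement_model(patients, ali)
        doubled_patients = patients + [
            Patient(p.patient_id + "_b", p.age, p.sex, engaged=p.engaged) for p in patients
        ]
        doubled_ali = dict(ali)
        for p in patients:
            doubled_ali[p.patient_id + "_b"] = ali[p.patient_id]
        double = engagement_model(doubled_patients, doubled_ali)
        assert double.coef_ali == pytest.approx(single.coef_ali, abs=1e-6)

    def test_complete_separation_flagged_unbounded(self):
        patients, ali = [], {}
        for i in range(40):
            v = 0.1 if i < 20 else 0.9
            pid = f"P{i}"
            patients.append(Patient(pid, 40.0, Sex.MALE, engaged=v > 0.5))
            ali[pid] = AliScore(pid, int(v * 10), 10, v)
        summary = engagement_model(patients, ali)
        assert summary.separation_flag
        assert summary.ci_low == -np.inf and summary.ci_high == np.inf
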