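"""Generator determinism, calibration, and truth-linked recovery."""

import numpy as np
import pytest
from pydantic import ValidationError as PydanticValidationError

from alirecovery import (
    ComponentId,
    GeneratorConfig,
    Status,
    discretize_records,
    expand_roadmap,
    generate_catalog,
    generate_cohort,
    recover,
    term_matches,
    write_fixture_bundle,
)
from alirecovery.data_model import (
    read_chart_review,
    read_cohort,
    read_diagnoses,
    read_icd10_catalog,
    read_biomarkers,
)
from alirecovery.roadmap import SearchTerm
from alirecovery.synthetic_data import noise_codes, read_truth


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(PydanticValidationError, match="measurement_prob"):
            GeneratorConfig(measurement_prob={c: 1.5 for c in ComponentId})

    def test_review_subset_larger_than_cohort_rejected(self):
        with pytest.raises(PydanticValidationError, match="review_size"):
            GeneratorConfig(n_patients=50, review_size=100)


class TestGenerateCatalog:
    def test_every_term_has_a_matching_code(self, original_roadmap, catalog):
        uni = expand_roadmap(original_roadmap, catalog)
        for comp in ComponentId:
            if original_roadmap.component_terms(comp):
                assert uni.component_codes(comp)

    def test_decoys_discriminate_token_from_substring(self, original_roadmap, catalog):
        token = expand_roadmap(original_roadmap, catalog, mode="token")
        substring = expand_roadmap(original_roadmap, catalog, mode="substring")
        token_all = set().union(*(token.component_codes(c) for c in ComponentId))
        sub_all = set().union(*(substring.component_codes(c) for c in ComponentId))
        assert token_all < sub_all  # decoys match only in substring mode

    def test_noise_codes_match_nothing(self, original_roadmap, catalog):
        terms = [t for c in ComponentId for t in original_roadmap.component_terms(c)]
        for code in noise_codes(catalog):
            desc = catalog.description(code)
            for t in terms:
                assert not term_matches(t, desc, "substring")


class TestGenerateCohort:
    def test_measurement_probability_one_means_no_missing(self, original_roadmap, catalog):
        config = GeneratorConfig(
            n_patients=30, seed=3, review_size=10,
            measurement_prob={c: 1.0 for c in ComponentId},
        )
        _, biomarkers, _, _, _ = generate_cohort(config, original_roadmap, catalog)
        assert all(r.value is not None for r in biomarkers)

    def test_values_discretize_to_true_status(self, small_study):
        sex = {p.patient_id: p.sex for p in small_study["patients"]}
        ehr = discretize_records(small_study["biomarkers"], sex)
        truth = small_study["truth"]
        for r in ehr:
            if r.status is not Status.MISSING:
                assert r.status is truth.true_status[(r.patient_id, r.component)]

    def test_perfect_sensitivity_recovers_exact_truth_set(self, original_roadmap, catalog):
        config = GeneratorConfig(
            n_patients=120, seed=5, review_size=20,
            carriage_sensitivity={c: 1.0 for c in ComponentId},
            false_carriage={c: 0.0 for c in ComponentId},
        )
        patients, biomarkers, diagnoses, _, truth = generate_cohort(
            config, original_roadmap, catalog
        )
        sex = {p.patient_id: p.sex for p in patients}
        ehr = discretize_records(biomarkers, sex)
        universe = expand_roadmap(original_roadmap, catalog)
        results = recover(ehr, diagnoses, universe)
        recoverable = {
            c for c in ComponentId if universe.component_codes(c)
        }
        expected = {
            (pid, comp)
            for (pid, comp), s in truth.true_status.items()
            if s is Status.UNHEALTHY
            and not truth.measured[(pid, comp)]
            and comp in recoverable
        }
        got = {(r.patient_id, r.component) for r in results if r.recovered}
        assert got == expected

    def test_review_subset_balanced_on_engagement(self, small_study):
        truth = small_study["truth"]
        engaged = {p.patient_id: p.engaged for p in small_study["patients"]}
        reviewed = truth.reviewed_patients
        assert len(reviewed) == small_study["config"].review_size
        n_eng = sum(engaged[p] for p in reviewed)
        assert abs(n_eng - len(reviewed) / 2) <= 1

    def test_chart_review_has_ten_records_per_reviewed_patient(self, small_study):
        chart = small_study["chart"]
        per_pid = {}
        for r in chart:
            per_pid.setdefault(r.patient_id, set()).add(r.component)
        assert set(per_pid) == set(small_study["truth"].reviewed_patients)
        assert all(comps == set(ComponentId) for comps in per_pid.values())


BIG_N = 5000


@pytest.fixture(scope="module")
def big_study(original_roadmap, catalog):
    config = GeneratorConfig(n_patients=BIG_N, seed=23, review_size=100)
    return config, generate_cohort(config, original_roadmap, catalog)


class TestCalibration:
    N = BIG_N

    def test_missingness_calibrated(self, big_study):
        config, (patients, biomarkers, _, _, _) = big_study
        missing = {c: 0 for c in ComponentId}
        for r in biomarkers:
            if r.value is None:
                missing[r.component] += 1
        for comp in ComponentId:
            rate = 1.0 - config.measurement_prob[comp]
            se = np.sqrt(max(rate * (1 - rate), 1e-9) * self.N)
            assert abs(missing[comp] - self.N * rate) <= 3 * se + 1, comp

    def test_carriage_sensitivity_calibrated(self, big_study, original_roadmap, catalog):
        config, (_, _, _, _, truth) = big_study
        universe = expand_roadmap(original_roadmap, catalog)
        for comp in ComponentId:
            if not universe.component_codes(comp):
                continue
            unhealthy = [
                truth.carriage[(pid, c)]
                for (pid, c), s in truth.true_status.items()
                if c is comp and s is Status.UNHEALTHY
            ]
            rate = config.carriage_sensitivity[comp]
            n = len(unhealthy)
            se = np.sqrt(max(rate * (1 - rate), 1e-9) / n)
            assert abs(np.mean(unhealthy) - rate) <= 3 * se + 1e-9, comp

    def test_engagement_rate_calibrated(self, big_study):
        config, (patients, _, _, _, truth) = big_study
        expected = np.mean([
            1 / (1 + np.exp(-(config.engagement_beta0
                              + config.engagement_beta1 * truth.true_ali[p.patient_id])))
            for p in patients
        ])
        observed = np.mean([p.engaged for p in patients])
        se = np.sqrt(expected * (1 - expected) / self.N)
        assert abs(observed - expected) <= 3 * se

    def test_noise_code_rate_calibrated(self, big_study):
        config, (_, _, diagnoses, _, _) = big_study
        n_noise = sum(1 for d in diagnoses if d.code.startswith("N"))
        mean = n_noise / self.N
        se = np.sqrt(config.noise_code_rate / self.N)  # Poisson
        assert abs(mean - config.noise_code_rate) <= 3 * se


class TestFixtureBundle:
    def test_round_trip(self, tmp_path, small_study, catalog):
        s = small_study
        paths = write_fixture_bundle(
            tmp_path, s["patients"], s["biomarkers"], s["diagnoses"],
            s["chart"], catalog, s["truth"],
        )
        assert read_cohort(paths["cohort"]) == s["patients"]
        assert read_chart_review(paths["chart_review"]) == s["chart"]
        back_bio = read_biomarkers(paths["biomarkers"])
        assert [(r.patient_id, r.component, r.value) for r in back_bio] == [
            (r.patient_id, r.component, r.value) for r in s["biomarkers"]
        ]
        back_cat = read_icd10_catalog(paths["icd10_catalog"])
        assert back_cat.codes == catalog.codes
        back_dx = read_diagnoses(paths["diagnoses"], back_cat)
        assert [(d.patient_id, d.code, d.date) for d in back_dx] == [
            (d.patient_id, d.code, d.date) for d in s["diagnoses"]
        ]
        truth = read_truth(paths["truth"])
        assert truth.true_status == s["truth"].true_status
        assert truth.true_ali == pytest.approx(s["truth"].true_ali)

    def test_same_seed_byte_identical(self, tmp_path, original_roadmap, catalog):
        config = GeneratorConfig(n_patients=25, seed=99, review_size=10)
        outs = []
        for sub in ("a", "b"):
            patients, bio, dx, chart, truth = generate_cohort(config, original_roadmap, catalog)
            outs.append(write_fixture_bundle(tmp_path / sub, patients, bio, dx,
                                             chart, catalog, truth))
        for key in outs[0]:
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes(), key

    def test_different_seeds_differ(self, original_roadmap, catalog):
        a = generate_cohort(GeneratorConfig(n_patients=25, seed=1, review_size=10),
                            original_roadmap, catalog)
        b = generate_cohort(GeneratorConfig(n_patients=25, seed=2, review_size=10),
                            original_roadmap, catalog)
        assert a[2] != b[2]  # diagnoses differ
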