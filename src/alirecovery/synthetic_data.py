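"""Synthetic EHR cohort generator with known ground truth.

Emulates the structure of the study data so every pipeline stage is testable
without external data: per-component missingness (near-total for
homocysteine and C-reactive protein, none for blood pressures), diagnosis
carriage correlated with true unhealthy status, background noise codes
(mean ~30 per patient), chart-review recovery including protocol errors,
and care engagement driven by the true allostatic load index through a
logistic model.

Everything is a deterministic function of the config seed: each generation
stage draws from its own child generator keyed ``(seed, stage)``, so adding
draws to one stage never perturbs another.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .data_model import (
    ChartReviewRecord,
    ComponentId,
    ComponentRecord,
    DiagnosisRecord,
    ICD10Catalog,
    Icd10Entry,
    Patient,
    Sex,
    Status,
    ValidationError,
    write_chart_review,
    write_cohort,
    write_diagnoses,
    write_icd10_catalog,
    write_biomarkers,
)
from .matching import MatchMode, expand_roadmap
from .phenotype import default_thresholds
from .roadmap import Roadmap

STUDY_START = _dt.date(2018, 3, 1)
STUDY_DAYS = 730  # two-year study period

# Plausible overall value range per component (clinical units); numeric draws
# are uniform within the band on the correct side of the threshold.
VALUE_RANGES: dict[ComponentId, tuple[float, float]] = {
    ComponentId.SBP: (100.0, 200.0),
    ComponentId.DBP: (60.0, 130.0),
    ComponentId.BMI: (18.0, 55.0),
    ComponentId.TRIG: (50.0, 500.0),
    ComponentId.CHOL: (120.0, 350.0),
    ComponentId.CRP: (0.1, 150.0),
    ComponentId.HBA1C: (4.5, 14.0),
    ComponentId.ALB: (2.0, 5.5),
    ComponentId.CC: (40.0, 180.0),
    ComponentId.HCST: (5.0, 150.0),
}

_EPS = 1e-3


def _default_measurement_prob() -> dict[ComponentId, float]:
    # 1 - missingness; blood pressures always measured, BMI nearly always,
    # CRP and homocysteine almost never, labs in between (~4 missing/patient).
    return {
        ComponentId.SBP: 1.0,
        ComponentId.DBP: 1.0,
        ComponentId.BMI: 0.998,
        ComponentId.TRIG: 0.59,
        ComponentId.CHOL: 0.59,
        ComponentId.CRP: 0.045,
        ComponentId.HBA1C: 0.59,
        ComponentId.ALB: 0.59,
        ComponentId.CC: 0.59,
        ComponentId.HCST: 0.017,
    }


def _default_prevalence() -> dict[ComponentId, float]:
    return {c: 0.33 for c in ComponentId}


def _default_sensitivity() -> dict[ComponentId, float]:
    # P(truly unhealthy patient carries >=1 roadmap-matching code)
    d = {c: 0.12 for c in ComponentId}
    d[ComponentId.CRP] = 0.90   # infection/sepsis codes are ubiquitous
    d[ComponentId.HCST] = 0.35
    return d


def _default_false_carriage() -> dict[ComponentId, float]:
    # P(truly healthy patient carries a matching code anyway)
    d = {c: 0.01 for c in ComponentId}
    d[ComponentId.CRP] = 0.45   # "infection" matches many mild diagnoses
    d[ComponentId.HCST] = 0.04
    return d


def _default_chart_recovery() -> dict[ComponentId, float]:
    # P(chart reviewer recovers a missing truly-unhealthy point); reviewers
    # see the whole chart, so this is independent of code carriage.
    d = {c: 0.15 for c in ComponentId}
    d[ComponentId.HCST] = 0.50
    d[ComponentId.CC] = 0.30
    return d


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic cohort generator."""

    n_patients: int = Field(default=1000, ge=1)
    seed: int = 0
    measurement_prob: dict[ComponentId, float] = Field(default_factory=_default_measurement_prob)
    prevalence: dict[ComponentId, float] = Field(default_factory=_default_prevalence)
    carriage_sensitivity: dict[ComponentId, float] = Field(default_factory=_default_sensitivity)
    false_carriage: dict[ComponentId, float] = Field(default_factory=_default_false_carriage)
    noise_code_rate: float = Field(default=30.0, ge=0)  # mean noise codes/patient
    chart_recovery_prob: dict[ComponentId, float] = Field(default_factory=_default_chart_recovery)
    protocol_error_prob: float = Field(default=0.02, ge=0, le=1)
    engagement_beta0: float = -1.25
    engagement_beta1: float = 1.5
    review_size: int = Field(default=100, ge=0)
    # logit shift applied to measurement probability for truly unhealthy
    # patients (missing-not-at-random knob); 0 = missingness independent of truth
    mnar_logit_shift: float = 0.0
    match_mode: MatchMode = "token"

    @field_validator(
        "measurement_prob", "prevalence", "carriage_sensitivity",
        "false_carriage", "chart_recovery_prob",
    )
    @classmethod
    def _probs_in_unit_interval(cls, v, info):
        for comp, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{info.field_name}[{comp}] = {p} outside [0, 1]")
        missing = set(ComponentId) - set(v)
        if missing:
            raise ValueError(
                f"{info.field_name} lacks entries for {sorted(c.value for c in missing)}"
            )
        return v

    @model_validator(mode="after")
    def _review_fits_cohort(self):
        if self.review_size > self.n_patients:
            raise ValueError(
                f"review_size ({self.review_size}) exceeds n_patients ({self.n_patients})"
            )
        return self


@dataclass
class SyntheticTruth:
    """Latent ground truth behind one generated cohort."""

    config: GeneratorConfig
    true_status: dict[tuple[str, ComponentId], Status]  # UNHEALTHY / HEALTHY
    true_ali: dict[str, float]  # unhealthy count / 10 on the latent truth
    carriage: dict[tuple[str, ComponentId], bool]  # planted matching code?
    measured: dict[tuple[str, ComponentId], bool]
    chart_recovered: set[tuple[str, ComponentId]]
    protocol_errors: set[tuple[str, ComponentId]]
    reviewed_patients: list[str]


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------

_AUX_PER_COMPONENT = 6


def aux_expansion_terms(component: ComponentId, n: int = _AUX_PER_COMPONENT) -> list[str]:
    """Synthetic auxiliary search terms (beyond the clinicians' roadmap) that
    the generated catalog carries codes for; the mock proposer's pool."""
    stem = component.value.lower()
    return [f"{stem}aux{j} disorder" for j in range(n)]


def _rand_word(rng: np.random.Generator, length: int = 7) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    return "".join(letters[i] for i in rng.integers(0, 26, size=length))


def generate_catalog(
    roadmap: Roadmap,
    n_decoys: int = 20,
    seed: int = 0,
    n_noise: int = 150,
    include_aux: bool = True,
) -> ICD10Catalog:
    """Synthetic ICD-10 catalog with three strata.

    * matched codes: per component, one code per roadmap term whose
      description contains every token of that term (plus filler words);
    * decoy codes: descriptions where each term token occurs only as a
      proper substring of a longer word, so substring mode matches but
      token mode does not;
    * noise codes: descriptions built from random words checked to contain
      no roadmap token even as a substring.

    When ``include_aux`` is set, additional codes matching the synthetic
    auxiliary expansion terms (see :func:`aux_expansion_terms`) are planted,
    so model-expanded roadmaps can recover strictly more than the original.
    """
    if roadmap.n_terms() == 0:
        raise ValidationError("generate_catalog requires a non-empty roadmap")
    rng = np.random.default_rng([seed, 101])
    catalog = ICD10Catalog()
    all_tokens: set[str] = set()

    counter = 0

    def next_code(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:02d}.{rng.integers(0, 10)}"

    filler = ["of", "the", "unspecified", "with", "chronic", "acute"]
    for comp in ComponentId:
        for term in sorted(roadmap.component_terms(comp), key=lambda t: t.normalized):
            all_tokens.update(term.tokens)
            words = list(term.tokens) + [filler[int(rng.integers(0, len(filler)))]]
            catalog.add(Icd10Entry(next_code("S"), " ".join(words).capitalize()))
    if include_aux:
        for comp in ComponentId:
            for raw in aux_expansion_terms(comp):
                toks = raw.split()
                all_tokens.update(toks)
                catalog.add(
                    Icd10Entry(next_code("A"), ("synthetic " + " ".join(toks)).capitalize())
                )

    # decoys: embed every token of a term inside a longer word
    terms_flat = [
        t for comp in ComponentId
        for t in sorted(roadmap.component_terms(comp), key=lambda t: t.normalized)
    ]
    for i in range(n_decoys):
        term = terms_flat[i % len(terms_flat)]
        words = ["x" + tok + "y" for tok in term.tokens]
        catalog.add(Icd10Entry(next_code("D"), " ".join(words).capitalize()))

    # noise: random words containing no roadmap/aux token even as substring
    for _ in range(n_noise):
        while True:
            words = [_rand_word(rng) for _ in range(3)]
            joined = " ".join(words)
            if not any(tok in joined for tok in all_tokens):
                break
        catalog.add(Icd10Entry(next_code("N"), joined.capitalize()))
    return catalog


def noise_codes(catalog: ICD10Catalog) -> list[str]:
    """Codes in the pure-noise stratum (match no roadmap or aux term)."""
    return sorted(e.code for e in catalog if e.code.startswith("N"))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_RACES = ["White or Caucasian", "Black or African American", "Other",
          "Asian Indian", "American Indian or Alaska Native"]
_RACE_P = [0.715, 0.181, 0.068, 0.030, 0.006]
_ETHNICITIES = ["Not Hispanic, Latino or Spanish", "Hispanic, Latino or Spanish",
                "Patient refused"]
_ETH_P = [0.934, 0.061, 0.005]


def _shifted_prob(p: float, shift: float) -> float:
    """Apply a logit shift to p, keeping the endpoints 0 and 1 fixed."""
    if shift == 0.0 or p <= 0.0 or p >= 1.0:
        return p
    logit = np.log(p / (1.0 - p)) + shift
    return float(1.0 / (1.0 + np.exp(-logit)))


def _draw_value(
    rng: np.random.Generator, comp: ComponentId, unhealthy: bool, sex: Sex
) -> float:
    rule = default_thresholds()[comp]
    cut = rule.cutoff_for(sex)
    lo, hi = VALUE_RANGES[comp]
    upper_is_unhealthy = rule.direction in ("greater", "greater_equal")
    boundary_unhealthy = rule.direction in ("greater_equal", "less_equal")
    if unhealthy == upper_is_unhealthy:
        a = cut if (unhealthy == boundary_unhealthy) else cut + _EPS
        b = hi
    else:
        a, b = lo, cut
    return float(rng.uniform(a, b))


def generate_cohort(
    config: GeneratorConfig,
    roadmap: Roadmap,
    catalog: ICD10Catalog,
) -> tuple[list[Patient], list[ComponentRecord], list[DiagnosisRecord],
           list[ChartReviewRecord], SyntheticTruth]:
    """Generate a full synthetic study: cohort, biomarkers (with MNAR-capable
    missingness), diagnoses (planted + noise), chart review with protocol
    errors, and the latent truth."""
    seed = config.seed
    rng_demo = np.random.default_rng([seed, 1])
    rng_truth = np.random.default_rng([seed, 2])
    rng_meas = np.random.default_rng([seed, 3])
    rng_dx = np.random.default_rng([seed, 4])
    rng_chart = np.random.default_rng([seed, 5])
    rng_engage = np.random.default_rng([seed, 6])
    rng_review = np.random.default_rng([seed, 7])

    universe = expand_roadmap(roadmap, catalog, mode=config.match_mode)
    noise_pool = noise_codes(catalog)

    n = config.n_patients
    width = len(str(n))
    pids = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    # demographics
    ages = rng_demo.integers(18, 66, size=n)
    sexes = [Sex.MALE if rng_demo.random() < 0.395 else Sex.FEMALE for _ in range(n)]
    races = [_RACES[i] for i in rng_demo.choice(len(_RACES), size=n, p=_RACE_P)]
    eths = [_ETHNICITIES[i] for i in rng_demo.choice(len(_ETHNICITIES), size=n, p=_ETH_P)]

    # latent truth
    true_status: dict[tuple[str, ComponentId], Status] = {}
    true_ali: dict[str, float] = {}
    for pid in pids:
        n_unhealthy = 0
        for comp in ComponentId:
            unhealthy = rng_truth.random() < config.prevalence[comp]
            true_status[(pid, comp)] = Status.UNHEALTHY if unhealthy else Status.HEALTHY
            n_unhealthy += unhealthy
        true_ali[pid] = n_unhealthy / len(ComponentId)

    # engagement: logistic on true ALI
    engaged = {
        pid: bool(
            rng_engage.random()
            < 1.0 / (1.0 + np.exp(-(config.engagement_beta0
                                    + config.engagement_beta1 * true_ali[pid])))
        )
        for pid in pids
    }

    patients = [
        Patient(pid, float(age), sex, race, eth, engaged[pid])
        for pid, age, sex, race, eth in zip(pids, ages, sexes, races, eths)
    ]
    sex_by_pid = {p.patient_id: p.sex for p in patients}

    # biomarker observation (MNAR knob: unhealthy shifts measurement odds)
    biomarkers: list[ComponentRecord] = []
    measured: dict[tuple[str, ComponentId], bool] = {}
    for pid in pids:
        for comp in ComponentId:
            p_meas = config.measurement_prob[comp]
            if true_status[(pid, comp)] is Status.UNHEALTHY:
                p_meas = _shifted_prob(p_meas, config.mnar_logit_shift)
            is_measured = rng_meas.random() < p_meas
            measured[(pid, comp)] = is_measured
            if is_measured:
                value = _draw_value(
                    rng_meas, comp,
                    true_status[(pid, comp)] is Status.UNHEALTHY,
                    sex_by_pid[pid],
                )
                biomarkers.append(ComponentRecord(pid, comp, value, Status.HEALTHY))
            else:
                biomarkers.append(ComponentRecord(pid, comp, None, Status.MISSING))

    # diagnoses: planted carriage + background noise
    diagnoses: list[DiagnosisRecord] = []
    carriage: dict[tuple[str, ComponentId], bool] = {}

    def _rand_date(rng: np.random.Generator) -> _dt.date:
        return STUDY_START + _dt.timedelta(days=int(rng.integers(0, STUDY_DAYS)))

    for pid in pids:
        for comp in ComponentId:
            matched = sorted(universe.component_codes(comp))
            p_carry = (
                config.carriage_sensitivity[comp]
                if true_status[(pid, comp)] is Status.UNHEALTHY
                else config.false_carriage[comp]
            )
            carries = bool(matched) and rng_dx.random() < p_carry
            carriage[(pid, comp)] = carries
            if carries:
                code = matched[int(rng_dx.integers(0, len(matched)))]
                diagnoses.append(DiagnosisRecord(pid, code, _rand_date(rng_dx)))
        k = int(rng_dx.poisson(config.noise_code_rate))
        if k and noise_pool:
            for idx in rng_dx.integers(0, len(noise_pool), size=k):
                diagnoses.append(DiagnosisRecord(pid, noise_pool[int(idx)], _rand_date(rng_dx)))

    # review subset: balanced 50/50 on engagement, topped up if one stratum
    # is too small
    eng_ids = [pid for pid in pids if engaged[pid]]
    non_ids = [pid for pid in pids if not engaged[pid]]
    rng_review.shuffle(eng_ids)
    rng_review.shuffle(non_ids)
    half = config.review_size // 2
    take_eng = min(half, len(eng_ids))
    take_non = min(config.review_size - take_eng, len(non_ids))
    reviewed = eng_ids[:take_eng] + non_ids[:take_non]
    if len(reviewed) < config.review_size:
        remainder = [pid for pid in eng_ids[take_eng:] if pid not in reviewed]
        reviewed += remainder[: config.review_size - len(reviewed)]
    reviewed = sorted(reviewed)

    # chart-review oracle
    chart: list[ChartReviewRecord] = []
    chart_recovered: set[tuple[str, ComponentId]] = set()
    protocol_errors: set[tuple[str, ComponentId]] = set()
    value_by_key = {(r.patient_id, r.component): r.value for r in biomarkers}
    for pid in reviewed:
        for comp in ComponentId:
            key = (pid, comp)
            if measured[key]:
                # validation arm: reviewer confirms the extracted value
                from .phenotype import discretize

                status = discretize(comp, value_by_key[key], sex_by_pid[pid])
                chart.append(ChartReviewRecord(pid, comp, status))
                continue
            if rng_chart.random() < config.protocol_error_prob:
                protocol_errors.add(key)
                chart.append(ChartReviewRecord(pid, comp, Status.PROTOCOL_ERROR))
                continue
            if (
                true_status[key] is Status.UNHEALTHY
                and rng_chart.random() < config.chart_recovery_prob[comp]
            ):
                chart_recovered.add(key)
                chart.append(ChartReviewRecord(pid, comp, Status.UNHEALTHY))
            else:
                chart.append(ChartReviewRecord(pid, comp, Status.MISSING))

    truth = SyntheticTruth(
        config=config,
        true_status=true_status,
        true_ali=true_ali,
        carriage=carriage,
        measured=measured,
        chart_recovered=chart_recovered,
        protocol_errors=protocol_errors,
        reviewed_patients=reviewed,
    )
    return patients, biomarkers, diagnoses, chart, truth


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    directory: str | Path,
    patients: Sequence[Patient],
    biomarkers: Sequence[ComponentRecord],
    diagnoses: Sequence[DiagnosisRecord],
    chart: Sequence[ChartReviewRecord],
    catalog: ICD10Catalog,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the full CSV bundle plus ``truth.json``; re-reading reproduces
    the in-memory objects, and a fixed seed yields a byte-identical bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": directory / "cohort.csv",
        "biomarkers": directory / "biomarkers.csv",
        "diagnoses": directory / "diagnoses.csv",
        "chart_review": directory / "chart_review.csv",
        "icd10_catalog": directory / "icd10_catalog.csv",
        "truth": directory / "truth.json",
    }
    write_cohort(patients, paths["cohort"])
    write_biomarkers(biomarkers, paths["biomarkers"])
    write_diagnoses(diagnoses, paths["diagnoses"])
    write_chart_review(chart, paths["chart_review"])
    write_icd10_catalog(catalog, paths["icd10_catalog"])
    payload = {
        "config": json.loads(truth.config.model_dump_json()),
        "true_status": {
            f"{pid}|{comp.value}": s.value for (pid, comp), s in truth.true_status.items()
        },
        "true_ali": truth.true_ali,
        "carriage": {
            f"{pid}|{comp.value}": bool(v) for (pid, comp), v in truth.carriage.items()
        },
        "measured": {
            f"{pid}|{comp.value}": bool(v) for (pid, comp), v in truth.measured.items()
        },
        "chart_recovered": sorted(f"{p}|{c.value}" for p, c in truth.chart_recovered),
        "protocol_errors": sorted(f"{p}|{c.value}" for p, c in truth.protocol_errors),
        "reviewed_patients": truth.reviewed_patients,
    }
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())

    def _key(s: str) -> tuple[str, ComponentId]:
        pid, comp = s.split("|")
        return pid, ComponentId(comp)

    return SyntheticTruth(
        config=GeneratorConfig(**payload["config"]),
        true_status={_key(k): Status(v) for k, v in payload["true_status"].items()},
        true_ali=payload["true_ali"],
        carriage={_key(k): v for k, v in payload["carriage"].items()},
        measured={_key(k): v for k, v in payload["measured"].items()},
        chart_recovered={_key(k) for k in payload["chart_recovered"]},
        protocol_errors={_key(k) for k in payload["protocol_errors"]},
        reviewed_patients=list(payload["reviewed_patients"]),
    )
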