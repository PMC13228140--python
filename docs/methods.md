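# Methods

## The recovery model

Each of a patient's ten allostatic load index (ALI) components is a data
point with a four-way status: UNHEALTHY, HEALTHY, MISSING, or (in chart
review data only) PROTOCOL_ERROR. Non-missing biomarker values are
discretized at clinical thresholds; missing ones may be *recovered* from
auxiliary evidence. The core assumption is one-sided: a relevant diagnosis
code is evidence of poor health, while the absence of one is not evidence
of good health. Recovery therefore only ever flips MISSING → UNHEALTHY;
non-missing statuses are immutable, and this invariant is asserted (not
silently corrected) in the evaluation layer.

The matching predicate is: a search term matches an ICD-10 code when every
word of the term appears in the code's description ("vitamin deficiency"
requires both "vitamin" and "deficiency"). Normalization lowercases,
replaces every non-alphanumeric character with whitespace, and splits on
whitespace; the same normalization applies to terms and descriptions so
matching is symmetric with parsing. Semantics are AND across a term's
tokens, OR across a component's terms, and strictly component-scoped.

Two occurrence modes are exposed because "appears" is ambiguous:

- `token` (default): each term token must occur as a whole token of the
  description. This prevents clinically absurd hits ("art" matching "Heart
  failure").
- `substring`: each token must occur as a substring. Kept as a comparison
  arm; the synthetic catalog plants decoy descriptions that separate the
  two modes, and the run mode is recorded in every report.

A patient-component point is recovered when the patient carries ≥1
diagnosis in the component's matched-code set, at any time in the study
period and with no lookback window (a found code marks the component
unhealthy for the whole study; a window option exists but defaults off).
Multiple dates of the same code are irrelevant: matching is
existence-based. Every recovery records all (code, term) evidence pairs to
support audit and adjudication.

## Thresholds and the ALI

Thresholds ship as data (`src/alirecovery/data/thresholds.yaml`), one rule
per component with the printed inequality strictness: SBP >140 mmHg,
DBP >90 mmHg, BMI >30 kg/m², triglycerides ≥150 mg/dL, total cholesterol
≥200 mg/dL, CRP ≥10 mg/L, HbA1c ≥6.5%, serum albumin ≥3.5 g/dL, creatinine
clearance <110 (males) / <100 (females) mL/min, homocysteine >50 µmol/L.
Creatinine clearance is the only sex-specific rule; discretizing it without
a known sex is an error. **Known anomaly:** the albumin direction is
implemented exactly as the source threshold table prints it (≥3.5 flags
unhealthy) even though low albumin is the conventional risk direction; the
rule is deliberately not "fixed" in code, and editing the YAML changes it
without a release.

ALI = unhealthy / non-missing by default (`denominator="nonmissing"`),
with `all10` available. The non-missing denominator is the default because
a fixed /10 denominator is implausible for cohorts averaging six observed
components with median ALI near 0.33. Under the non-missing denominator,
recovering any point can only raise a patient's ALI (it appends a 1 to a
mean of values ≤ 1) — an invariant the tests exercise.

## Adjudication

Clinician adjudication keeps exactly the items endorsed by at least one
reviewer. Term-level verdicts filter term sets directly (an empty ledger
endorses nothing and yields an empty roadmap); code-level verdicts operate
on matched ICD-10 codes, and codes reviewed without endorsement become a
per-roadmap exclusion list applied after matching — both granularities are
supported because review can happen on proposed terms or on the codes they
matched. Adjudication is contractive (output universe ⊆ input universe) and
idempotent, which makes the recovery ordering between an adjudicated
roadmap and its parent a theorem rather than an empirical observation.

## Expansion

The proposer contract isolates everything model-specific: a proposer is
called once per iteration with per-component metadata (and, in `context`
mode, the clinicians' example terms, which it is expected to echo back) and
returns candidate terms. Iterations are independent — fresh session each
call — so earlier output cannot bias later output. The aggregate roadmap is
the superset (set union after normalization) of all proposals, which is
order-invariant; the saturation curve counts unique matched catalog codes
after each iteration and is non-decreasing by construction. The default of
20 iterations follows the self-consistency design this emulates. A plateau
is operationally defined as the first iteration after which the cumulative
matched-code count never grows by more than a tolerance (default 0); the
definition is ours, since "plateau" has no canonical quantitative meaning.
Live API adapters are out of the tested surface; the shipped proposers are
a seeded mock (bit-reproducible) and a recorded-fixture replayer.

## Synthetic data generator

The generator emulates the structure of a two-year primary-care EHR study
with N = 1000 adults aged 18–65; all defaults were fixed once, before any
result-dependent tuning, and are documented as assumptions rather than
claims:

- **Missingness** per component (probability a biomarker is unmeasured):
  SBP/DBP 0, BMI 0.002, triglycerides/cholesterol/HbA1c/albumin/creatinine
  clearance 0.41, CRP 0.955, homocysteine 0.983. This yields ≈4 missing
  components per patient (median 4, total ≈4000/10 000) with blood
  pressures always present and inflammatory labs almost never — the
  qualitative pattern of routine care. An optional MNAR knob
  (`mnar_logit_shift`) shifts the measurement odds for truly unhealthy
  patients; it defaults to 0 (independent) but is exercised in tests.
- **Truth and values**: each component is truly unhealthy with prevalence
  0.33; observed values are drawn uniformly within a plausible band on the
  correct side of the threshold. The marginal value distribution is
  deliberately simple — the pipeline consumes only discretized statuses.
- **Diagnosis carriage**: a truly unhealthy patient carries ≥1 matching
  code with per-component sensitivity (default 0.12; CRP 0.90, homocysteine
  0.35), a healthy patient with a false-carriage rate (default 0.01; CRP
  0.45 — "infection" matches many mild diagnoses, the main source of
  algorithm-only disagreements). Poisson background noise codes (mean
  30/patient) come from a stratum constructed to match no term even as a
  substring.
- **Catalog**: per roadmap term a code whose description contains the
  term's tokens; decoy codes embedding each token inside longer words
  (separating token from substring mode); noise codes; and auxiliary codes
  matching synthetic expansion-only terms, so expanded roadmaps can recover
  strictly more than the original.
- **Chart review**: 100 patients sampled 50/50 on engagement (the adaptive
  residual-based second sampling wave of the emulated design is not
  reproduced; simple balanced sampling stands in). The review confirms
  observed values, recovers missing truly-unhealthy points with
  per-component probability (default 0.15; homocysteine 0.50, creatinine
  clearance 0.30 — reviewers see information the algorithm cannot), and
  stamps protocol errors on missing points with probability 0.02. Chart
  recovery is independent of code carriage, which produces the chart-only
  disagreement type.
- **Engagement**: Bernoulli with logit(p) = β₀ + β₁·(true ALI), β₀ = −1.25,
  β₁ = 1.5, giving an engagement rate ≈0.32.

Determinism: every stage draws from `numpy.random.default_rng([seed, k])`
with a fixed stage index k, so a fixed seed gives byte-identical fixture
bundles and adding draws to one stage cannot perturb another.

What passing tests on this generator do *not* show: real ICD-10 code
frequency distributions, correlated comorbidity structure, real MNAR
mechanisms, free-text evidence, or coding-practice drift. The generator
validates the algorithm's logic and the estimators' calibration, not
clinical performance.

## Evaluation conventions

- Quantiles use linear interpolation (numpy default); fixed so IQR
  assertions are deterministic.
- Percentages are rounded to 0 decimals in human-readable output and kept
  at full precision in JSON.
- Protocol errors are reclassified to MISSING (with an audit flag) before
  any comparison; the algorithm may still recover them.
- The engagement model is a maximum-likelihood logistic regression of the
  engagement flag on ALI with Wald 95% intervals (statsmodels). Patients
  with undefined ALI are excluded and counted; a constant-ALI design is
  flagged degenerate; suspected complete separation is flagged and the
  interval reported unbounded.

## Problem sizes

The test suite and acceptance script use cohorts of 150–5000 patients and
200-replicate coverage runs at n = 500 — sizes at which binomial/Wald error
bounds are tight enough to detect calibration faults while keeping the full
suite fast. The acceptance script's main study is N = 1000 with a
100-patient review subset, mirroring the emulated design, and checks slope
recovery on a separate n = 5000 cohort where the Monte-Carlo error on the
logistic slope is small.

## Known limitations

- Roadmap semantics cannot express negation, severity grading, or context
  ("history of X" matches X's tokens).
- Token matching cannot bridge compounding ("auto immune" does not match
  "autoimmune"); no stemming, fuzzy matching, or ontology mapping.
- The recovery algorithm is existence-based in time; no lookback windows.
- Numeric values are never imputed — output is statuses only.
- The naive and augmented engagement fits on observed ALI are attenuated
  relative to the truth-based fit (measurement error in ALI); the package
  reports both rather than correcting for it.
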