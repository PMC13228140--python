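# alirecovery

Roadmap-driven recovery of missing allostatic load index (ALI) components
from ICD-10 diagnosis codes, with a synthetic-EHR test bench.

## The problem

The ALI is a computable phenotype for physiological "wear and tear": the
proportion of ten biomarkers — systolic/diastolic blood pressure, body mass
index, triglycerides, total cholesterol, C-reactive protein, hemoglobin A1c,
serum albumin, creatinine clearance, homocysteine — that fall in the
unhealthy range at clinically-driven thresholds,

```
ALI_i = (# unhealthy components) / (# non-missing components)   for patient i.
```

In routinely collected EHR data many of these biomarkers are unmeasured,
and because measurement depends on clinical decisions the missingness is
missing-not-at-random. Expert chart reviews can recover some missing values
using a clinician-authored *roadmap* of auxiliary search terms (e.g.
"Sepsis" or "infection" implies an elevated C-reactive protein), but chart
review does not scale.

This package implements the scalable alternative: an algorithm that matches
each roadmap term against ICD-10 code descriptions (a term matches when
**every** word of the term appears in the description), builds per-component
matched-code sets, and flips a patient's MISSING component to UNHEALTHY
whenever the patient carries at least one matching diagnosis. Around that
core it provides:

- **roadmap** handling: parsing, normalization, grade-enumeration expansion
  ("Grade I, II, or III obesity" → three terms), diffing, and clinician
  adjudication (keep terms/codes endorsed by ≥1 reviewer);
- **expansion**: a self-consistency loop that aggregates the superset of
  terms proposed across many independent proposer invocations, with
  saturation diagnostics — the proposer is a pluggable contract, shipped
  with a deterministic mock and a recorded-fixture replayer (no live API in
  the tested path);
- **phenotype**: threshold discretization (thresholds ship as editable
  YAML) and ALI computation;
- **evaluation**: status-flow accounting with the one-sided recovery rule
  enforced, missingness summaries, chart-vs-algorithm disagreement
  taxonomy, ALI distribution shifts, and a logistic regression of care
  engagement on ALI;
- **synthetic_data**: a fully seeded generator of cohorts, ICD-10 catalogs
  (with token/substring-discriminating decoys), diagnoses, MNAR-capable
  biomarker missingness, and chart-review oracles with known ground truth.

## Worked example

```bash
alirecovery simulate --seed 7 --n-patients 1000 --out study/
alirecovery recover  --bundle study/ --out run/
```

prints

```
recovered 805 of 4085 missing data points (20%)
```

meaning: of the 10 × 1000 synthetic data points, 4085 biomarkers were
missing in the extracted-EHR table, and the algorithm — using the shipped
clinicians' roadmap (20 search terms) against the synthetic catalog —
flipped 805 of them to unhealthy on diagnosis-code evidence. Each recovery
is written to `run/recovery_results.csv` with the (code, term) pairs that
justified it, and `run/match_report.json` holds the per-component matched
code sets. `alirecovery evaluate --bundle study/ --out eval/` then produces
the full report: flow tables, per-patient/per-component missingness,
chart-vs-algorithm disagreements, the ALI shift (median 0.33 → 0.40 under
defaults), and the engagement regression.

The same pipeline is available as a library:

```python
import alirecovery as ali

rm = ali.load_original_roadmap()
catalog = ali.generate_catalog(rm, seed=7)
cfg = ali.GeneratorConfig(n_patients=1000, seed=7)
patients, bio, dx, chart, truth = ali.generate_cohort(cfg, rm, catalog)
sex = {p.patient_id: p.sex for p in patients}
ehr = ali.discretize_records(bio, sex)
universe = ali.expand_roadmap(rm, catalog)          # term -> matched codes
results = ali.recover(ehr, dx, universe)            # MISSING -> UNHEALTHY only
print(ali.recovery_counts(results))
```

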