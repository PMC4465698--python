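# poagpheno

Rule-based phenotyping of **primary open-angle glaucoma (POAG)** from
de-identified electronic medical records (EMR).

Ophthalmology clinics often file exam results as scanned paper forms, so the
gold standard for glaucoma — serial fundus photography — is invisible to
EMR research databases. This package implements the alternative: a
transparent decision tree over what *is* searchable — ICD-9 diagnosis
codes, CPT procedure codes, medication mentions, and free clinical text —
that classifies each subject as a POAG case or control, adjudicates cases
into confidence tiers, mines cup-to-disc ratios (CDR) out of referral
letters, derives study covariates, and scores the algorithm against chart
review. It is aimed at EMR/biobank phenotyping for genetic association
studies, where a reviewable, auditable rule set matters more than a black
box.

## The algorithm

Per subject, as of a census date (default 2013-03-20):

1. **Eligibility** — age > 20 years (year-resolution, from birth year) and
   ≥ 1 CPT code for an ophthalmology exam (92002/92004/92012/92014/92250)
   or general clinic visit (99201–99215).
2. **Case branch** — any ICD-9 **365.11** (POAG) event makes a case
   candidate; other glaucoma subtype codes do not disqualify. Candidates
   are adjudicated:
   * `case_definite`: an ophthalmologist/optometrist letter states the
     subtype ("primary open-angle glaucoma"), **or** the record has ≥ 2
     365.11 events on distinct dates **and** a glaucoma medication **and**
     a POAG surgery phrase (e.g. selective laser trabeculoplasty) in a
     surgical report;
   * `case_potential`: 365.11 + a fundus/exam CPT (92012/92014/92250) + a
     glaucoma medication + a text mention of "POAG"/"glaucoma" in a clinic
     note or problem list;
   * `case_indeterminate` otherwise — "advanced glaucoma", "ocular
     hypertension", "glaucoma suspect" and other-subtype diagnoses
     (uveitic, chronic angle closure, pediatric, neovascular, steroid
     responder) never count toward case evidence.
3. **Control branch** — control iff the record is devoid of any glaucoma
   ICD-9 code (365.x), none of seven glaucoma spelling variants
   (glaucoma, glaucome, glocoma, gloucoma, gluacoma, glucoma, glycoma)
   appears in problem lists or clinic notes, and age ≥ 40.

Performance against chart review uses PPV = TP/(TP+FP), NPV = TN/(TN+FN),
accuracy = (TP+TN)/(TP+FP+TN+FN) in exact rational arithmetic, formatted
with a truncating (floor) percent formatter.

Because the source EMR is private, the package ships a seeded
synthetic-cohort generator whose archetypes exercise every branch of the
tree with exact ground-truth labels and planted CDR values.

## Worked example

```bash
python examples/classify_cohort.py
```

```
status counts:
  case_definite            20
  case_indeterminate       11
  case_potential           10
  control                  110
  excluded_from_controls   25
  ineligible               24
agreement with planted labels: 200/200
example assignment: S00000 -> case_definite
  reasons: POAG_ICD_PRESENT, DIAGNOSIS_STATEMENT_POAG
```

A 200-subject synthetic cohort is generated, the decision tree assigns each
subject exactly one status, and every assignment matches the label the
generator intended — including the trap archetypes (misspelled mentions,
glaucoma suspects, other subtypes) that land in the excluded/indeterminate
bins rather than contaminating cases or controls. The reason codes make
each decision auditable.

```bash
python examples/review_metrics.py
```

```
definite cases:
  PPV      = 51.6%   (138/267)
  accuracy = 76.3%   (433/567)
definite + potential cases:
  PPV      = 76.7%   (205/267)
controls:
  NPV      = 98.3%   (295/300)
```

Given review counts — 267 flagged cases of which 138 were confirmed
definite and 67 potential, and 300 reviewed controls with 5 errors — these
are the algorithm's chart-review operating characteristics: barely half of
flagged cases are definite POAG (downstream review required), but controls
are nearly always true controls.

Other examples: `examples/extract_cdr_values.py` (CDR mining and
most-recent-per-eye selection) and `examples/covariate_table.py` (index
dates, hypertension rule, two-year windowed medians).

## Command line

```bash
poag-phenotype generate --seed 3 --n-subjects 500 --out cohort/
poag-phenotype classify --cohort cohort/ --as-of 2013-03-20 --out results/
poag-phenotype extract-cdr --cohort cohort/ --out results/
poag-phenotype covariates --cohort cohort/ --out results/
poag-phenotype evaluate --assignments results/assignments.csv \
    --truth cohort/truth.csv --out results/metrics.json
```

A cohort directory holds `demographics.csv`, `coded_events.csv`,
`medications.csv`, `measurements.csv` and `documents.jsonl`; all rule
parameters (code sets, term lists, thresholds) live in a YAML lexicon that
`--lexicon` can override.

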