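# Methods

## Problem setting

Primary open-angle glaucoma (POAG) is the most common glaucoma subtype and
disproportionately affects African Americans. In EMR-linked biobanks the
diagnostic gold standard (serial fundus photographs) is typically absent
from the research-accessible record, because eye clinics often keep
scanned paper charts outside the structured EMR. Case/control status must
therefore be inferred from billing codes and free clinical text. This
package implements such a rule-based phenotyping algorithm, plus the
instrumentation needed to study it: a free-text miner for cup-to-disc
ratios, covariate derivation, chart-review performance arithmetic, and a
synthetic-cohort generator that stands in for the private source records.

## Data model

A cohort is a directory of plain-text files (CSV + JSONL) holding, per
subject: demographics (birth **year** only — the de-identified source
supplies year-level age, so all ages are integer year differences), dated
ICD-9/CPT coded events, dated medication mentions, dated vital/laboratory
measurements, and dated free-text documents tagged with a provenance type
(`ophtho_letter`, `surgical_report`, `problem_list`, `clinic_note`).
Dates are ISO-8601; every interval comparison is closed. Unparseable rows
are quarantined into a load report, never silently dropped, so accepted +
quarantined always equals input rows.

## The decision tree

* **Eligibility**: age strictly over 20 at the census date (default
  2013-03-20, configurable) and at least one ophthalmology or
  general-clinic CPT code. The age floor excludes pediatric glaucoma,
  which is a genetically distinct condition.
* **Case candidacy**: ≥ 1 ICD-9 365.11 event. Codes for other glaucoma
  subtypes do not disqualify (mixed-mechanism disease and progression
  between subtypes are common).
* **Definite tier**: either a written POAG diagnosis statement found in an
  `ophtho_letter` document — the provenance tag stands in for "written by
  an ophthalmologist/optometrist" — or triple evidence: two 365.11 events
  on **distinct calendar dates** (same-day duplicate billing is one
  encounter), a glaucoma medication, and a surgery phrase (argon /
  selective / MicroPulse laser trabeculoplasty, Ex-Press mini shunt) in a
  `surgical_report`. The surgery criterion matches report text rather than
  CPT surgery codes, because the design ties it to the surgical report; a
  configurable CPT surgery list could additionally satisfy it.
* **Potential tier**: 365.11 + fundus/exam CPT (92012/92014/92250) +
  glaucoma medication + a countable text mention of "POAG" or "glaucoma"
  in a clinic note or problem list.
* **Countable text evidence**: mentions embedded in an ambiguity phrase
  ("advanced glaucoma", "ocular hypertension", "glaucoma suspect") or in
  another-subtype diagnosis ("neovascular glaucoma", …) never count toward
  POAG status. When such embedded mentions are the *only* textual glaucoma
  evidence, the indeterminate assignment carries `OTHER_SUBTYPE_ONLY` /
  `AMBIGUOUS_PHRASE` reason codes for reviewer triage.
* **Controls**: no 365.x ICD-9 code, none of the seven spelling variants
  in problem lists or clinic notes, age ≥ 40 (younger clean records risk
  being future cases). Variant matching is **substring**, not whole-word:
  a crude free-text exclusion errs toward dropping candidate controls and
  also catches derived forms such as "glaucomatous". Subjects failing only
  the control conditions get `excluded_from_controls`; subjects with a
  non-POAG glaucoma code and no 365.11 fall through both arms into the
  same bin — they are in neither study group.

Every subject receives exactly one status; case tiers and controls are
disjoint by construction.

## CDR extraction

Key phrases `CDR`, `C/D`, `cup-to-disc [ratio]`, `cup-to-disk [ratio]`
(case-insensitive, hyphen/space tolerant) are matched; one or two decimal
values in [0, 1] are accepted within a **40-character window** after the
phrase — a bounded window prevents cross-sentence capture. Laterality
comes from the nearest `OD`/`O.D.`/"right eye" or `OS`/`O.S.`/"left eye"
marker within 25 characters of the value (ties prefer the marker following
the value, the dominant "0.7 OD" convention), or from an `OD/OS`
positional pair over a `x/y` value pair; otherwise `unspecified`. An
adjoining "horizontal"/"vertical" token sets the axis field; an `H/V`
quotient is left `unspecified` rather than guessed — clinicians report
horizontal, vertical, and quotient CDRs interchangeably, and that
ambiguity is surfaced to the caller instead of silently resolved.
Phrase hits with no value in the window are tallied in an extraction
report (real records contain them); every accepted value carries its
verbatim source span. Most-recent selection is per eye, with date ties
broken by later position in the document, then extraction order.

## Covariates

Cases anchor on the earliest 365.11 date ("age at diagnosis"); controls on
the latest CPT date ("last clinic visit"). The two-year window is read as
a centered interval |date − index| ≤ 730 days (configurable). Hypertension
is any in-window SBP > 140 mm Hg, DBP > 90 mm Hg (strict inequalities, any
single qualifying value counts — same-day values are not aggregated), or
an antihypertensive mention; the antihypertensive list is a documented
reconstruction of the standard classes, separate from the glaucoma
medication list. Windowed summaries are medians (even counts: mean of the
middle two).

## Performance metrics

Confusion counts are exhaustive 2×2 tallies; PPV/NPV/sensitivity/
specificity/accuracy are exact `Fraction`s, and a denominator of zero is
an error, never 0. The default percent formatter **truncates** (floors)
at one decimal: with review counts 138/267, 433/567, 205/267, 295/300 it
prints 51.6 / 76.3 / 76.7 / 98.3, which is consistent with published
reports of this algorithm family only under truncation (rounding would
give 51.7 / 76.4 / 76.8 / 98.3). Conventional rounding is available by
flag. For definite-tier metrics, potential cases remain in the
positive-prediction denominator (267); for potential-inclusive metrics
TP = definite + potential = 205. One published companion value — an
"83.1%" potential-inclusive accuracy — is not derivable from any natural
combination of the printed counts ((205+295)/567 = 88.1%) and is therefore
not reproduced here.

## Synthetic cohorts

The generator is adversarial-by-design, not distributionally realistic:
each archetype plants exactly the evidence pattern one branch of the tree
keys on, including the documented traps (misspelled mentions, glaucoma
suspects, other subtypes, under-age clean records). Note text is
template-based so extraction ground truth is exact; the template set
*defines* the surface-form grammar the extractor guarantees. Defaults
encode the study conditions: census date 2013-03-20, case/control ages
centred on 62/54 years (SD 12/11.7), 60% female, per-eye CDR values drawn
from a clipped normal centred on 0.7 (SD 0.22, rounded to 2 decimals),
value-free CDR mentions at rate 9/132, BMI centred on 30.1 kg/m². Blood
pressures use clinically typical between-subject spreads (SBP SD 15, DBP
SD 10 mm Hg) rather than the wide dispersions of the source cohort table,
because what the hypertension rule exercises is the threshold-crossing
rate, and the wide spreads would make nearly every subject hypertensive;
covariate streams add within-subject noise of SD 5 around a subject-level
mean and are clipped to physiological ranges. Each subject draws from a
`numpy` generator seeded by (seed, subject index), so cohorts are
byte-stable and insensitive to archetype reordering; archetype counts use
largest-remainder apportionment.

Passing tests on these cohorts show the implementation is faithful to the
stated rules and that the extractor is exact **on its documented
grammar**. They do not show robustness to real clinical prose (OCR noise,
negation, tables, section headers), and the fixture mix is not a
prevalence model.

## Numerical and procedural choices

* Ages are integer year differences (year-level de-identification);
  eligibility is strict (> 20), the control floor inclusive (≥ 40).
* Metric arithmetic is exact rational; truncation/rounding happen only at
  formatting, via integer floor/half-up on the scaled fraction (no
  floating-point percent artifacts).
* Acceptance/regression runs use cohorts of 200–1500 subjects — large
  enough that every archetype appears tens to hundreds of times and
  sample medians sit within a few hundredths of their targets, small
  enough to run in seconds.
* The lexicon is immutable after load; overrides are validated (e.g. the
  POAG code must stay inside the configured glaucoma ICD-9 family).

## Known limitations

* Fig-list code sets and the institutional medication table of the source
  study are not public; the shipped ICD-9/CPT defaults and drug lists are
  labeled reconstructions (the full 365.x family as "any glaucoma code";
  standard drug classes), all configurable.
* No negation handling or section segmentation: "no glaucoma" excludes a
  control and "family history of glaucoma" counts as a mention — matching
  the deliberately crude free-text search this algorithm family uses.
* Whether the two independent 365.11 mentions must come from distinct
  documents (vs distinct dates, as implemented) and whether the definite
  triple additionally requires an ophthalmology CPT are underdetermined by
  the published rules; distinct dates / no extra CPT were chosen and are
  noted here.
* The algorithm is tuned to one institution's record-keeping; portability
  of the lexicon defaults to other EMRs is untested.
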