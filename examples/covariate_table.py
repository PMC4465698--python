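"""Derive index dates and windowed covariates, then print the cohort table.

Cases anchor on the date of their first POAG ICD-9 (365.11) event, controls
on their last clinic-visit CPT date.  Within a centered two-year window the
subject is classified hypertensive (SBP > 140, DBP > 90, or an
antihypertensive mention) and per-kind medians (BMI, blood pressures,
lipids) are taken.  The summary row per status tier mirrors a standard
study-population characteristics table.
"""

from poagpheno import build_profile, default_lexicon, run_phenotyping, summarize_cohort
from poagpheno.synthetic_cohort import CohortRecipe, generate_cohort

lexicon = default_lexicon()
cohort = generate_cohort(CohortRecipe(seed=21, n_subjects=300))
assignments = run_phenotyping(cohort.records, lexicon=lexicon)

by_sid = {r.subject_id: r for r in cohort.records}
profiles = [
    build_profile(by_sid[a.subject_id], a, lexicon)
    for a in assignments
    if a.status in ("case_definite", "case_potential", "case_indeterminate", "control")
]

table = summarize_cohort(profiles, assignments, cohort.records)
cols = ["status", "n", "median_age_at_index", "pct_female", "pct_hypertensive", "median_bmi"]
print(table[cols].round(1).to_string(index=False))
print("\n(ages anchor on diagnosis for cases and last clinic visit for controls)")
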