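"""Index dates, hypertension classification, and windowed covariate summaries.

The per-subject anchor ("index") date is the first POAG ICD-9 (365.11) event
for cases — the date of diagnosis as recorded in billing — and the last
clinic-visit CPT event for controls.  Covariates are computed in a centered
two-year window around that date: a subject is hypertensive if any in-window
systolic pressure exceeds 140 mm Hg, any diastolic exceeds 90 mm Hg (strict
inequalities), or an antihypertensive medication is mentioned; laboratory
and anthropometric covariates are in-window medians.
"""

from __future__ import annotations

import datetime as dt
import statistics
from dataclasses import dataclass, field

import pandas as pd

from .emr_model import Measurement, PatientRecord, age_at
from .lexicons import AlgorithmLexicon
from .phenotyper import PhenotypeAssignment

__all__ = [
    "CovariateProfile",
    "index_date",
    "is_hypertensive",
    "windowed_median",
    "build_profile",
    "summarize_cohort",
]

CASE_TIERS = ("case_definite", "case_potential", "case_indeterminate")
SUMMARY_KINDS = ("bmi", "sbp", "dbp", "total_cholesterol", "hdl", "ldl", "triglycerides")


@dataclass(frozen=True)
class CovariateProfile:
    subject_id: str
    index_date: dt.date
    index_kind: str               # "diagnosis" | "last_clinic_visit"
    age_at_index: int
    hypertensive: bool
    windowed_medians: dict[str, float] = field(default_factory=dict)


def index_date(
    record: PatientRecord,
    assignment: PhenotypeAssignment,
    lexicon: AlgorithmLexicon,
) -> tuple[dt.date, str]:
    """Earliest 365.11 date for case tiers; latest CPT date for controls."""
    if assignment.status in CASE_TIERS:
        dates = [
            e.event_date
            for e in record.coded_events
            if e.code_system == "ICD9" and e.code == lexicon.poag_icd9
        ]
        if not dates:
            raise ValueError(
                f"subject {record.subject_id} assigned {assignment.status} "
                f"but has no {lexicon.poag_icd9} event"
            )
        return min(dates), "diagnosis"
    if assignment.status == "control":
        dates = [e.event_date for e in record.coded_events if e.code_system == "CPT"]
        if not dates:
            raise ValueError(f"control {record.subject_id} has no CPT event")
        return max(dates), "last_clinic_visit"
    raise ValueError(f"no index date defined for status {assignment.status}")


def _in_window(date: dt.date, index: dt.date, window_days: int) -> bool:
    return abs((date - index).days) <= window_days


def is_hypertensive(
    record: PatientRecord,
    index: dt.date,
    lexicon: AlgorithmLexicon,
) -> bool:
    """Any in-window SBP > 140, DBP > 90, or antihypertensive mention."""
    w = lexicon.covariate_window_days
    for m in record.measurements:
        if not _in_window(m.measure_date, index, w):
            continue
        if m.kind == "sbp" and m.value > lexicon.sbp_threshold:
            return True
        if m.kind == "dbp" and m.value > lexicon.dbp_threshold:
            return True
    return any(
        med.drug_name in lexicon.hypertension_medications
        and _in_window(med.mention_date, index, w)
        for med in record.medications
    )


def windowed_median(
    measurements: list[Measurement],
    kind: str,
    index: dt.date,
    lexicon: AlgorithmLexicon,
) -> float | None:
    """Median of in-window values of *kind*; None when no value is in window.

    An even count takes the mean of the two middle values.
    """
    values = [
        m.value
        for m in measurements
        if m.kind == kind and _in_window(m.measure_date, index, lexicon.covariate_window_days)
    ]
    if not values:
        return None
    return float(statistics.median(values))


def build_profile(
    record: PatientRecord,
    assignment: PhenotypeAssignment,
    lexicon: AlgorithmLexicon,
) -> CovariateProfile:
    idx, kind = index_date(record, assignment, lexicon)
    medians = {}
    for mk in SUMMARY_KINDS:
        v = windowed_median(record.measurements, mk, idx, lexicon)
        if v is not None:
            medians[mk] = v
    return CovariateProfile(
        subject_id=record.subject_id,
        index_date=idx,
        index_kind=kind,
        age_at_index=age_at(record.demographics, idx),
        hypertensive=is_hypertensive(record, idx, lexicon),
        windowed_medians=medians,
    )


def summarize_cohort(
    profiles: list[CovariateProfile],
    assignments: list[PhenotypeAssignment],
    records: list[PatientRecord],
) -> pd.DataFrame:
    """Cohort-description table: one row per status tier.

    Columns: N, median age at index, % female (with denominator), %
    hypertensive, and the across-subject median of each per-subject windowed
    median.  Percentages use non-missing denominators.
    """
    status_of = {a.subject_id: a.status for a in assignments}
    sex_of = {r.subject_id: r.demographics.sex for r in records}
    prof_by_sid = {p.subject_id: p for p in profiles}

    rows = []
    tiers = sorted({a.status for a in assignments if a.subject_id in prof_by_sid})
    for tier in tiers:
        sids = [sid for sid, st in status_of.items() if st == tier and sid in prof_by_sid]
        profs = [prof_by_sid[s] for s in sids]
        if not profs:
            continue
        sexes = [sex_of[s] for s in sids if sex_of.get(s) in ("female", "male")]
        row: dict[str, object] = {
            "status": tier,
            "n": len(profs),
            "median_age_at_index": float(statistics.median(p.age_at_index for p in profs)),
            "pct_female": 100.0 * sum(s == "female" for s in sexes) / len(sexes) if sexes else None,
            "n_sex_known": len(sexes),
            "pct_hypertensive": 100.0 * sum(p.hypertensive for p in profs) / len(profs),
        }
        for mk in SUMMARY_KINDS:
            vals = [p.windowed_medians[mk] for p in profs if mk in p.windowed_medians]
            row[f"median_{mk}"] = float(statistics.median(vals)) if vals else None
            row[f"n_{mk}"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)
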