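"""Seeded generator of labeled synthetic EMR cohorts.

The source records this package was designed for are private, so testing and
demonstration run on synthetic cohorts built from adversarial archetypes —
one per branch of the decision tree: definite cases evidenced by an
ophthalmology letter or by the code/medication/surgery triple, potential
cases, other-subtype and "glaucoma suspect" confounders, misspelled
free-text mentions, clean controls, under-age contaminants, and ineligible
records.  Note text is template-based (no free generation) so extraction
ground truth is exact; the template set enumerates the surface-form grammar
the CDR extractor supports.

Determinism: each subject draws from its own ``numpy`` Generator seeded by
(seed, subject index), so cohorts are byte-stable and unaffected by
archetype reordering.  Planted study conditions follow the published cohort
description: case age centred on 62 years and controls on 54, ~60% female,
cup-to-disc values centred on 0.7 per eye, BMI median 30.1, and a 9/132
rate of value-free CDR mentions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emr_model import (
    ClinicalDocument,
    CodedEvent,
    Demographics,
    Measurement,
    MedicationMention,
    PatientRecord,
    write_cohort,
)

__all__ = ["CohortRecipe", "SyntheticCohort", "generate_cohort", "ARCHETYPES"]

ARCHETYPES = (
    "definite_by_letter",
    "definite_by_triple_evidence",
    "potential",
    "other_subtype_confounder",
    "ambiguous_suspect",
    "misspelled_text_only",
    "clean_control",
    "under_age_control_contaminant",
    "ineligible_no_cpt",
    "ineligible_young",
)

DEFAULT_MIX = {
    "definite_by_letter": 0.05,
    "definite_by_triple_evidence": 0.05,
    "potential": 0.05,
    "other_subtype_confounder": 0.04,
    "ambiguous_suspect": 0.04,
    "misspelled_text_only": 0.04,
    "clean_control": 0.55,
    "under_age_control_contaminant": 0.06,
    "ineligible_no_cpt": 0.06,
    "ineligible_young": 0.06,
}

_CASE_ARCHETYPES = ("definite_by_letter", "definite_by_triple_evidence", "potential")

# planted covariate distributions: kind -> (location, scale), case / control.
# Locations follow the cohort-description medians (BMI 30.1 etc.).  Blood
# pressures use clinically typical between-subject spreads instead of the
# table dispersions: what the hypertension rule exercises is the rate of
# threshold crossings, and those spreads put it near the reported ~50%.
_COVARIATE_DIST = {
    "bmi": ((30.1, 6.7), (30.1, 8.0)),
    "sbp": ((134.5, 15.0), (124.0, 15.0)),
    "dbp": ((74.5, 10.0), (80.0, 10.0)),
    "total_cholesterol": ((183.0, 40.6), (161.0, 65.2)),
    "hdl": ((52.5, 25.0), (53.0, 38.6)),
    "ldl": ((103.0, 42.9), (99.0, 50.7)),
    "triglycerides": ((125.0, 76.3), (98.0, 67.8)),
}

#: probability of an antihypertensive mention near the anchor date
_HTN_MED_P = 0.3

_SURGERY_PHRASES = (
    "selective laser trabeculoplasty",
    "argon laser trabeculoplasty",
    "micropulse laser trabeculoplasty",
    "ex-press mini glaucoma shunt",
)
_GLAUCOMA_MEDS = ("latanoprost", "timolol", "brimonidine", "dorzolamide", "bimatoprost")
_HTN_MEDS = ("lisinopril", "hydrochlorothiazide", "amlodipine", "metoprolol", "losartan")
_MISSPELLINGS = ("glaucome", "glocoma", "gloucoma", "gluacoma", "glucoma", "glycoma")
_OTHER_SUBTYPES = (
    "uveitic glaucoma",
    "chronic angle closure glaucoma",
    "pediatric glaucoma",
    "neovascular glaucoma",
    "glaucoma steroid responder",
)


@dataclass(frozen=True)
class CohortRecipe:
    seed: int = 0
    n_subjects: int = 200
    mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    as_of: dt.date = dt.date(2013, 3, 20)
    cdr_median: float = 0.7
    cdr_sd: float = 0.22
    cdr_miss_rate: float = 9 / 132
    case_age: tuple[float, float] = (62.0, 12.0)
    control_age: tuple[float, float] = (54.0, 11.7)
    pct_female: float = 0.60

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        unknown = set(self.mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    truth: pd.DataFrame                 # subject_id, archetype, intended_status, cdr_od, cdr_os
    planted_cdr: pd.DataFrame           # every planted value: subject_id, eye, value, doc_date
    n_cdr_misses: int                   # planted value-free CDR mentions
    recipe: CohortRecipe

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(self.records, out)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.planted_cdr.to_csv(out / "planted_cdr.csv", index=False)


def _apportion(n: int, mix: dict[str, float]) -> list[str]:
    """Largest-remainder apportionment of n subjects over archetypes (stable)."""
    quotas = [(a, n * mix.get(a, 0.0)) for a in ARCHETYPES]
    counts = {a: int(q) for a, q in quotas}
    short = n - sum(counts.values())
    by_frac = sorted(quotas, key=lambda aq: (aq[1] - int(aq[1]), ARCHETYPES.index(aq[0])), reverse=True)
    for a, _ in by_frac[:short]:
        counts[a] += 1
    out: list[str] = []
    for a in ARCHETYPES:
        out.extend([a] * counts[a])
    return out


def _date(rng: np.random.Generator, lo_year: int = 2005, hi_year: int = 2012) -> dt.date:
    return dt.date(2000, 1, 1) + dt.timedelta(
        days=int(rng.integers((lo_year - 2000) * 365, (hi_year - 2000) * 365))
    )


def _cdr_value(rng: np.random.Generator, recipe: CohortRecipe) -> float:
    v = rng.normal(recipe.cdr_median, recipe.cdr_sd)
    return round(float(np.clip(v, 0.05, 0.95)), 2)


def _plant_cdr_notes(
    sid: str,
    rng: np.random.Generator,
    recipe: CohortRecipe,
    doc_start: int,
) -> tuple[list[ClinicalDocument], list[dict], int]:
    """CDR clinic notes with exact ground truth; returns (docs, truth rows, misses)."""
    docs: list[ClinicalDocument] = []
    truth: list[dict] = []
    misses = 0
    n_notes = int(rng.integers(1, 4))
    start = _date(rng, 2005, 2010)
    # distinct dates so the most-recent-per-eye ground truth is unambiguous
    offsets = sorted(int(o) for o in rng.choice(900, size=n_notes, replace=False))
    dates = [start + dt.timedelta(days=o) for o in offsets]
    for k, date in enumerate(dates):
        doc_id = f"{sid}-cdr{doc_start + k}"
        if rng.random() < recipe.cdr_miss_rate:
            text = "Optic nerves examined. CDR stable bilaterally, see prior drawing."
            misses += 1
            docs.append(ClinicalDocument(doc_id, sid, "clinic_note", date, text))
            continue
        od, os_ = _cdr_value(rng, recipe), _cdr_value(rng, recipe)
        template = int(rng.integers(0, 5))
        if template == 0:
            text = f"Exam today. Cup-to-disc ratio of {od} OD and {os_} OS. RTC in six months."
            planted = [("OD", od), ("OS", os_)]
        elif template == 1:
            text = f"Slit lamp unremarkable. CDR {od} O.D., {os_} O.S."
            planted = [("OD", od), ("OS", os_)]
        elif template == 2:
            text = f"Fundus: C/D OD/OS: {od}/{os_}. Maculae flat."
            planted = [("OD", od), ("OS", os_)]
        elif template == 3:
            text = f"Vertical cup-to-disc ratio {od} OD, {os_} OS; fields full."
            planted = [("OD", od), ("OS", os_)]
        else:
            text = f"Note: cup to disk ratio {od}/{os_} recorded without laterality."
            planted = [("unspecified", od), ("unspecified", os_)]
        docs.append(ClinicalDocument(doc_id, sid, "clinic_note", date, text))
        for eye, val in planted:
            truth.append({"subject_id": sid, "eye": eye, "value": val,
                          "doc_date": date.isoformat(), "document_id": doc_id})
    return docs, truth, misses


# plausibility clamps per kind so generated streams stay physiological
_COVARIATE_CLIP = {
    "bmi": (14.0, 75.0),
    "sbp": (75.0, 250.0),
    "dbp": (40.0, 150.0),
    "total_cholesterol": (70.0, 500.0),
    "hdl": (10.0, 150.0),
    "ldl": (20.0, 350.0),
    "triglycerides": (30.0, 1500.0),
}

#: within-subject measurement noise (the location/scale table above describes
#: between-subject spread of per-subject typical values)
_WITHIN_SD = 5.0


def _covariate_stream(
    sid: str,
    rng: np.random.Generator,
    anchor: dt.date,
    is_case: bool,
) -> tuple[list[Measurement], list[MedicationMention]]:
    out: list[Measurement] = []
    col = 0 if is_case else 1
    for kind, dists in _COVARIATE_DIST.items():
        loc, scale = dists[col]
        lo, hi = _COVARIATE_CLIP[kind]
        subject_mu = float(np.clip(rng.normal(loc, scale), lo, hi))
        for _ in range(3):
            value = round(float(np.clip(rng.normal(subject_mu, _WITHIN_SD), lo, hi)), 1)
            offset = int(rng.integers(-600, 601))
            out.append(Measurement(sid, kind, value, anchor + dt.timedelta(days=offset)))
    meds: list[MedicationMention] = []
    if rng.random() < _HTN_MED_P:
        meds.append(
            MedicationMention(
                sid, str(rng.choice(_HTN_MEDS)),
                anchor + dt.timedelta(days=int(rng.integers(-300, 301))),
            )
        )
    return out, meds


def _birth_year(rng: np.random.Generator, recipe: CohortRecipe, kind: str) -> int:
    yr = recipe.as_of.year
    if kind == "case":
        loc, scale = recipe.case_age
        age = int(np.clip(rng.normal(loc, scale), 41, 95))
    elif kind == "control":
        loc, scale = recipe.control_age
        age = int(np.clip(rng.normal(loc, scale), 40, 95))
    elif kind == "young_adult":
        age = int(rng.integers(21, 40))
    else:  # child / adolescent, at most 20 as of the census date
        age = int(rng.integers(5, 21))
    return yr - age


def _build_subject(
    index: int,
    archetype: str,
    recipe: CohortRecipe,
) -> tuple[PatientRecord, dict, list[dict], int]:
    rng = np.random.default_rng([recipe.seed, index])
    sid = f"S{index:05d}"
    sex = "female" if rng.random() < recipe.pct_female else "male"
    events: list[CodedEvent] = []
    meds: list[MedicationMention] = []
    docs: list[ClinicalDocument] = []
    measurements: list[Measurement] = []
    cdr_truth: list[dict] = []
    misses = 0
    intended = "control"

    is_case = archetype in _CASE_ARCHETYPES
    age_kind = (
        "case" if is_case or archetype == "other_subtype_confounder"
        else "young_adult" if archetype == "under_age_control_contaminant"
        else "child" if archetype == "ineligible_young"
        else "control"
    )
    birth_year = _birth_year(rng, recipe, age_kind)

    if archetype == "definite_by_letter":
        intended = "case_definite"
        dx = _date(rng)
        events.append(CodedEvent(sid, "ICD9", "365.11", dx))
        events.append(CodedEvent(sid, "CPT", "92014", dx))
        docs.append(
            ClinicalDocument(
                f"{sid}-letter", sid, "ophtho_letter", dx + dt.timedelta(days=14),
                "Dear Doctor, thank you for the referral. "
                "Impression: primary open-angle glaucoma, OU. "
                "We will begin topical therapy and follow closely.",
            )
        )
        cdr_docs, cdr_truth, misses = _plant_cdr_notes(sid, rng, recipe, 0)
        docs.extend(cdr_docs)
        cov_ms, cov_meds = _covariate_stream(sid, rng, dx, True)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "definite_by_triple_evidence":
        intended = "case_definite"
        d1 = _date(rng, 2005, 2010)
        d2 = d1 + dt.timedelta(days=int(rng.integers(30, 400)))
        events.append(CodedEvent(sid, "ICD9", "365.11", d1))
        events.append(CodedEvent(sid, "ICD9", "365.11", d2))
        events.append(CodedEvent(sid, "CPT", "92014", d1))
        meds.append(MedicationMention(sid, str(rng.choice(_GLAUCOMA_MEDS)), d2))
        phrase = str(rng.choice(_SURGERY_PHRASES))
        docs.append(
            ClinicalDocument(
                f"{sid}-surg", sid, "surgical_report", d2 + dt.timedelta(days=30),
                f"Operative report: {phrase} performed on the right eye "
                "without complication. Patient tolerated the procedure well.",
            )
        )
        cdr_docs, cdr_truth, misses = _plant_cdr_notes(sid, rng, recipe, 0)
        docs.extend(cdr_docs)
        cov_ms, cov_meds = _covariate_stream(sid, rng, d1, True)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "potential":
        intended = "case_potential"
        dx = _date(rng)
        events.append(CodedEvent(sid, "ICD9", "365.11", dx))
        events.append(CodedEvent(sid, "CPT", "92250", dx))
        meds.append(MedicationMention(sid, str(rng.choice(_GLAUCOMA_MEDS)), dx))
        docs.append(
            ClinicalDocument(
                f"{sid}-pl", sid, "problem_list", dx,
                "Problem list: glaucoma; hypertension; hyperlipidemia.",
            )
        )
        cdr_docs, cdr_truth, misses = _plant_cdr_notes(sid, rng, recipe, 0)
        docs.extend(cdr_docs)
        cov_ms, cov_meds = _covariate_stream(sid, rng, dx, True)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "other_subtype_confounder":
        intended = "case_indeterminate"
        dx = _date(rng)
        subtype = str(rng.choice(_OTHER_SUBTYPES))
        events.append(CodedEvent(sid, "ICD9", "365.11", dx))
        events.append(CodedEvent(sid, "CPT", "99213", dx))
        docs.append(
            ClinicalDocument(
                f"{sid}-note", sid, "clinic_note", dx,
                f"Assessment: {subtype}, followed by outside ophthalmology.",
            )
        )
        cov_ms, cov_meds = _covariate_stream(sid, rng, dx, True)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "ambiguous_suspect":
        d0 = _date(rng)
        has_code = bool(rng.random() < 0.5)
        intended = "case_indeterminate" if has_code else "excluded_from_controls"
        if has_code:
            events.append(CodedEvent(sid, "ICD9", "365.11", d0))
        events.append(CodedEvent(sid, "CPT", "99213", d0))
        phrase = str(rng.choice(["glaucoma suspect", "glaucoma suspect, ocular hypertension"]))
        docs.append(
            ClinicalDocument(
                f"{sid}-note", sid, "clinic_note", d0,
                f"Elevated IOP noted. Patient is a {phrase}; monitor annually.",
            )
        )
        cov_ms, cov_meds = _covariate_stream(sid, rng, d0, False)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "misspelled_text_only":
        intended = "excluded_from_controls"
        d0 = _date(rng)
        events.append(CodedEvent(sid, "CPT", "99213", d0))
        docs.append(
            ClinicalDocument(
                f"{sid}-note", sid, "clinic_note", d0,
                f"Per outside records patient carries a history of {rng.choice(_MISSPELLINGS)}.",
            )
        )
        cov_ms, cov_meds = _covariate_stream(sid, rng, d0, False)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "clean_control":
        intended = "control"
        visits = sorted(_date(rng) for _ in range(int(rng.integers(2, 5))))
        for v in visits:
            events.append(CodedEvent(sid, "CPT", "99213", v))
        docs.append(
            ClinicalDocument(
                f"{sid}-note", sid, "clinic_note", visits[-1],
                "Annual physical. Chronic conditions reviewed and stable.",
            )
        )
        cov_ms, cov_meds = _covariate_stream(sid, rng, visits[-1], False)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "under_age_control_contaminant":
        intended = "excluded_from_controls"
        d0 = _date(rng)
        events.append(CodedEvent(sid, "CPT", "99213", d0))
        docs.append(
            ClinicalDocument(f"{sid}-note", sid, "clinic_note", d0,
                             "Well visit, no acute complaints.")
        )
        cov_ms, cov_meds = _covariate_stream(sid, rng, d0, False)
        measurements, meds = measurements + cov_ms, meds + cov_meds

    elif archetype == "ineligible_no_cpt":
        intended = "ineligible"
        d0 = _date(rng)
        events.append(CodedEvent(sid, "ICD9", "401.9", d0))
        docs.append(
            ClinicalDocument(f"{sid}-note", sid, "clinic_note", d0,
                             "Telephone encounter; refill requested.")
        )

    elif archetype == "ineligible_young":
        intended = "ineligible"
        d0 = _date(rng)
        events.append(CodedEvent(sid, "CPT", "99213", d0))

    record = PatientRecord(
        demographics=Demographics(sid, birth_year, sex, "African American"),
        coded_events=events,
        medications=meds,
        measurements=measurements,
        documents=docs,
    )
    record.validate()

    latest: dict[str, tuple[str, float]] = {}
    for row in cdr_truth:
        key = row["eye"]
        cur = latest.get(key)
        if cur is None or row["doc_date"] >= cur[0]:
            latest[key] = (row["doc_date"], row["value"])
    truth_row = {
        "subject_id": sid,
        "archetype": archetype,
        "intended_status": intended,
        "cdr_od": latest.get("OD", (None, None))[1],
        "cdr_os": latest.get("OS", (None, None))[1],
    }
    return record, truth_row, cdr_truth, misses


def generate_cohort(recipe: CohortRecipe) -> SyntheticCohort:
    """Build a labeled cohort; deterministic given ``recipe.seed``."""
    archetypes = _apportion(recipe.n_subjects, recipe.mix)
    records: list[PatientRecord] = []
    truth_rows: list[dict] = []
    cdr_rows: list[dict] = []
    misses = 0
    for i, arch in enumerate(archetypes):
        rec, truth_row, cdr_truth, m = _build_subject(i, arch, recipe)
        records.append(rec)
        truth_rows.append(truth_row)
        cdr_rows.extend(cdr_truth)
        misses += m
    truth = pd.DataFrame(
        truth_rows, columns=["subject_id", "archetype", "intended_status", "cdr_od", "cdr_os"]
    )
    planted = pd.DataFrame(
        cdr_rows, columns=["subject_id", "eye", "value", "doc_date", "document_id"]
    )
    return SyntheticCohort(records, truth, planted, misses, recipe)
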