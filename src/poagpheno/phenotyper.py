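"""The POAG case/control decision tree and manual-review adjudication tiers.

Flow, per subject, as of a reference census date:

1. **Eligibility** — age strictly over 20 and at least one ophthalmology or
   general-clinic CPT code; otherwise ``ineligible``.
2. **Case branch** — any ICD-9 365.11 event makes the subject a case
   candidate (other glaucoma subtype codes do not disqualify).  Candidates
   are adjudicated:

   * ``case_definite`` if an ophthalmologist/optometrist letter states the
     POAG subtype explicitly, OR the record carries the triple evidence —
     two 365.11 events on distinct calendar dates, a glaucoma medication,
     and a POAG surgery phrase in a surgical report;
   * ``case_potential`` if the record has a 365.11 event, a fundus/ophtho
     exam CPT (92012/92014/92250), a glaucoma medication, AND a text mention
     of "POAG" or "glaucoma" in a clinic note or problem list;
   * ``case_indeterminate`` otherwise — with reason codes noting when the
     only textual glaucoma evidence is another subtype or an ambiguous
     phrase ("advanced glaucoma", "ocular hypertension", "glaucoma
     suspect"), which never count toward case status.

3. **Control branch** — eligible non-candidates are controls iff their
   record is devoid of any glaucoma ICD-9 code (the 365.x family), the
   seven glaucoma spelling variants never appear in problem lists or
   clinical notes, and age is at least 40 (younger records risk being
   future cases).  Failures land in ``excluded_from_controls``.

Every subject gets exactly one status; the assignment carries ordered
machine-readable reason codes for audit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .emr_model import PatientRecord, age_at
from .lexicons import AlgorithmLexicon, is_glaucoma_icd9
from .text_mining import detect_diagnosis_statements, find_case_text_mentions, find_terms

__all__ = [
    "PhenotypeAssignment",
    "DEFAULT_AS_OF",
    "screen_eligibility",
    "classify_case_candidate",
    "classify_control",
    "adjudicate_case",
    "run_phenotyping",
]

#: default census date for age computation
DEFAULT_AS_OF = dt.date(2013, 3, 20)

STATUSES = (
    "ineligible",
    "case_definite",
    "case_potential",
    "case_indeterminate",
    "control",
    "excluded_from_controls",
)

# reason codes
AGE_BELOW_MIN = "AGE_BELOW_MIN"
NO_QUALIFYING_CPT = "NO_QUALIFYING_CPT"
POAG_ICD_PRESENT = "POAG_ICD_PRESENT"
GLAUCOMA_ICD_PRESENT = "GLAUCOMA_ICD_PRESENT"
TWO_INDEPENDENT_POAG_CODES = "TWO_INDEPENDENT_POAG_CODES"
GLAUCOMA_MED_PRESENT = "GLAUCOMA_MED_PRESENT"
POAG_SURGERY_PRESENT = "POAG_SURGERY_PRESENT"
DIAGNOSIS_STATEMENT_POAG = "DIAGNOSIS_STATEMENT_POAG"
FUNDUS_CPT_PRESENT = "FUNDUS_CPT_PRESENT"
CASE_TEXT_MENTION = "CASE_TEXT_MENTION"
OTHER_SUBTYPE_ONLY = "OTHER_SUBTYPE_ONLY"
AMBIGUOUS_PHRASE = "AMBIGUOUS_PHRASE"
TEXT_GLAUCOMA_MENTION = "TEXT_GLAUCOMA_MENTION"


@dataclass(frozen=True)
class PhenotypeAssignment:
    subject_id: str
    status: str
    reasons: tuple[str, ...] = ()
    as_of_date: dt.date = DEFAULT_AS_OF

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def screen_eligibility(
    record: PatientRecord,
    as_of: dt.date,
    lexicon: AlgorithmLexicon,
) -> tuple[bool, list[str]]:
    """Age strictly over ``case_min_age`` and at least one qualifying CPT code."""
    reasons: list[str] = []
    if age_at(record.demographics, as_of) <= lexicon.case_min_age:
        reasons.append(AGE_BELOW_MIN)
    has_cpt = any(
        e.code_system == "CPT" and e.code in lexicon.eligibility_cpt
        for e in record.coded_events
    )
    if not has_cpt:
        reasons.append(NO_QUALIFYING_CPT)
    return not reasons, reasons


def classify_case_candidate(record: PatientRecord, lexicon: AlgorithmLexicon) -> bool:
    """At least one ICD-9 event with the POAG code (365.11).

    Additional codes for other glaucoma subtypes do not disqualify: mixed-
    mechanism disease and progression between subtypes are common.
    """
    return any(
        e.code_system == "ICD9" and e.code == lexicon.poag_icd9
        for e in record.coded_events
    )


def classify_control(
    record: PatientRecord,
    as_of: dt.date,
    lexicon: AlgorithmLexicon,
) -> tuple[bool, list[str]]:
    """Record devoid of glaucoma codes and glaucoma text, and age >= 40."""
    reasons: list[str] = []
    if any(
        e.code_system == "ICD9" and is_glaucoma_icd9(e.code, lexicon)
        for e in record.coded_events
    ):
        reasons.append(GLAUCOMA_ICD_PRESENT)
    search_docs = [d for d in record.documents if d.doc_type in ("problem_list", "clinic_note")]
    if find_terms(search_docs, lexicon.glaucoma_spelling_variants, whole_word=False):
        reasons.append(TEXT_GLAUCOMA_MENTION)
    if age_at(record.demographics, as_of) < lexicon.control_min_age:
        reasons.append(AGE_BELOW_MIN)
    return not reasons, reasons


def _has_surgery_phrase(record: PatientRecord, lexicon: AlgorithmLexicon) -> bool:
    reports = [d for d in record.documents if d.doc_type == "surgical_report"]
    return bool(find_terms(reports, lexicon.poag_surgery_phrases, whole_word=False))


def adjudicate_case(
    record: PatientRecord,
    lexicon: AlgorithmLexicon,
) -> tuple[str, list[str]]:
    """Assign a case candidate to the definite / potential / indeterminate tier."""
    reasons: list[str] = [POAG_ICD_PRESENT]

    statements = detect_diagnosis_statements(record.documents, lexicon)
    # the written-subtype criterion requires an ophthalmologist/optometrist
    # letter, which the document provenance tag stands in for
    letter_ids = {d.document_id for d in record.documents if d.doc_type == "ophtho_letter"}
    poag_letter = any(
        s.subtype_label == "POAG" and s.document_id in letter_ids for s in statements
    )

    poag_dates = {
        e.event_date
        for e in record.coded_events
        if e.code_system == "ICD9" and e.code == lexicon.poag_icd9
    }
    has_med = any(m.drug_name in lexicon.glaucoma_medications for m in record.medications)
    has_surgery = _has_surgery_phrase(record, lexicon)

    if poag_letter:
        return "case_definite", reasons + [DIAGNOSIS_STATEMENT_POAG]
    if len(poag_dates) >= 2 and has_med and has_surgery:
        return "case_definite", reasons + [
            TWO_INDEPENDENT_POAG_CODES,
            GLAUCOMA_MED_PRESENT,
            POAG_SURGERY_PRESENT,
        ]

    has_fundus_cpt = any(
        e.code_system == "CPT" and e.code in lexicon.fundus_cpt for e in record.coded_events
    )
    text_mentions = find_case_text_mentions(record.documents, lexicon)
    if poag_dates and has_fundus_cpt and has_med and text_mentions:
        return "case_potential", reasons + [
            FUNDUS_CPT_PRESENT,
            GLAUCOMA_MED_PRESENT,
            CASE_TEXT_MENTION,
        ]

    # indeterminate: note when the only textual glaucoma evidence is another
    # subtype or an ambiguous phrase — neither counts toward case status
    labels = {s.subtype_label for s in statements}
    subtype_labels = set(lexicon.subtype_labels)
    if not text_mentions:
        if labels & subtype_labels and not (labels & {"POAG", "general_glaucoma"}):
            reasons.append(OTHER_SUBTYPE_ONLY)
        if "ambiguous" in labels and not (labels & {"POAG", "general_glaucoma"}):
            reasons.append(AMBIGUOUS_PHRASE)
    return "case_indeterminate", reasons


def run_phenotyping(
    cohort: list[PatientRecord],
    as_of: dt.date = DEFAULT_AS_OF,
    lexicon: AlgorithmLexicon | None = None,
) -> list[PhenotypeAssignment]:
    """Apply the full decision tree, producing exactly one status per subject."""
    if lexicon is None:
        from .lexicons import default_lexicon

        lexicon = default_lexicon()
    seen: set[str] = set()
    out: list[PhenotypeAssignment] = []
    for record in cohort:
        sid = record.subject_id
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r} in cohort")
        seen.add(sid)

        eligible, elig_reasons = screen_eligibility(record, as_of, lexicon)
        if not eligible:
            out.append(PhenotypeAssignment(sid, "ineligible", tuple(elig_reasons), as_of))
            continue
        if classify_case_candidate(record, lexicon):
            status, reasons = adjudicate_case(record, lexicon)
            out.append(PhenotypeAssignment(sid, status, tuple(reasons), as_of))
            continue
        ok, ctrl_reasons = classify_control(record, as_of, lexicon)
        if ok:
            out.append(PhenotypeAssignment(sid, "control", (), as_of))
        else:
            out.append(
                PhenotypeAssignment(sid, "excluded_from_controls", tuple(ctrl_reasons), as_of)
            )
    return out


def status_counts(assignments: list[PhenotypeAssignment]) -> dict[str, int]:
    counts = {s: 0 for s in STATUSES}
    for a in assignments:
        counts[a.status] += 1
    return counts
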