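import datetime as dt
import random

import pytest

from poagpheno import (
    CodedEvent,
    adjudicate_case,
    classify_case_candidate,
    classify_control,
    run_phenotyping,
    screen_eligibility,
)
from poagpheno.phenotyper import (
    AGE_BELOW_MIN,
    AMBIGUOUS_PHRASE,
    NO_QUALIFYING_CPT,
    OTHER_SUBTYPE_ONLY,
    TEXT_GLAUCOMA_MENTION,
)

from conftest import AS_OF, make_record


class TestEligibility:
    def test_adult_with_ophtho_cpt_is_eligible(self, lexicon):
        ok, reasons = screen_eligibility(make_record(birth_year=1950), AS_OF, lexicon)
        assert ok and reasons == []

    def test_age_20_or_under_is_ineligible(self, lexicon):
        ok, reasons = screen_eligibility(make_record(birth_year=1994), AS_OF, lexicon)
        assert not ok and AGE_BELOW_MIN in reasons
        ok21, _ = screen_eligibility(make_record(birth_year=1992), AS_OF, lexicon)
        assert ok21  # strictly over 20 -> 21 qualifies

    def test_no_qualifying_cpt_is_ineligible(self, lexicon):
        ok, reasons = screen_eligibility(make_record(cpt=()), AS_OF, lexicon)
        assert not ok and reasons == [NO_QUALIFYING_CPT]


class TestCaseCandidate:
    def test_single_poag_code_qualifies(self, lexicon):
        assert classify_case_candidate(make_record(icd9=("365.11",)), lexicon)

    def test_additional_subtype_code_does_not_disqualify(self, lexicon):
        assert classify_case_candidate(make_record(icd9=("365.11", "365.23")), lexicon)

    def test_unspecified_glaucoma_code_alone_does_not_qualify(self, lexicon):
        assert not classify_case_candidate(make_record(icd9=("365.9",)), lexicon)


class TestControl:
    def test_clean_older_record_is_control(self, lexicon):
        ok, reasons = classify_control(make_record(birth_year=1958), AS_OF, lexicon)
        assert ok and reasons == []

    def test_misspelled_text_mention_excludes(self, lexicon):
        rec = make_record(docs=[("clinic_note", "pt reports glucoma dx elsewhere")])
        ok, reasons = classify_control(rec, AS_OF, lexicon)
        assert not ok and reasons == [TEXT_GLAUCOMA_MENTION]

    def test_under_40_excluded_as_future_case_risk(self, lexicon):
        ok, reasons = classify_control(make_record(birth_year=1974), AS_OF, lexicon)
        assert not ok and reasons == [AGE_BELOW_MIN]

    def test_text_scan_covers_only_problem_lists_and_clinic_notes(self, lexicon):
        rec = make_record(docs=[("surgical_report", "glaucoma procedure performed")])
        ok, _ = classify_control(rec, AS_OF, lexicon)
        assert ok


class TestAdjudication:
    def test_letter_statement_makes_definite(self, lexicon):
        rec = make_record(
            icd9=("365.11",),
            docs=[("ophtho_letter", "Impression: primary open-angle glaucoma, OU")],
        )
        status, _ = adjudicate_case(rec, lexicon)
        assert status == "case_definite"

    def test_triple_evidence_makes_definite(self, lexicon):
        rec = make_record(
            icd9=(("365.11", "2008-01-01"), ("365.11", "2009-01-01")),
            meds=("latanoprost",),
            docs=[("surgical_report", "selective laser trabeculoplasty performed")],
        )
        status, _ = adjudicate_case(rec, lexicon)
        assert status == "case_definite"

    def test_same_day_duplicate_codes_are_one_mention(self, lexicon):
        rec = make_record(
            icd9=(("365.11", "2008-01-01"), ("365.11", "2008-01-01")),
            meds=("latanoprost",),
            docs=[("surgical_report", "selective laser trabeculoplasty performed")],
        )
        status, _ = adjudicate_case(rec, lexicon)
        assert status != "case_definite"

    def test_code_cpt_med_and_text_make_potential(self, lexicon):
        rec = make_record(
            cpt=("92250",),
            icd9=("365.11",),
            meds=("timolol",),
            docs=[("problem_list", "Problems: glaucoma; HTN")],
        )
        status, _ = adjudicate_case(rec, lexicon)
        assert status == "case_potential"

    def test_other_subtype_only_is_indeterminate(self, lexicon):
        rec = make_record(
            icd9=("365.11",), docs=[("clinic_note", "neovascular glaucoma secondary to PDR")]
        )
        status, reasons = adjudicate_case(rec, lexicon)
        assert status == "case_indeterminate" and OTHER_SUBTYPE_ONLY in reasons

    def test_ambiguous_phrases_never_support_case_status(self, lexicon):
        rec = make_record(
            cpt=("92250",),
            icd9=("365.11",),
            meds=("timolol",),
            docs=[("clinic_note", "patient is a glaucoma suspect")],
        )
        status, reasons = adjudicate_case(rec, lexicon)
        assert status == "case_indeterminate" and AMBIGUOUS_PHRASE in reasons


class TestDecisionTree:
    def test_three_fixture_cohort_gets_three_statuses(self, lexicon):
        cohort = [
            make_record(
                sid="A",
                icd9=("365.11",),
                docs=[("ophtho_letter", "primary open-angle glaucoma confirmed")],
            ),
            make_record(sid="B", birth_year=1955),
            make_record(sid="C", birth_year=1996),
        ]
        statuses = {a.subject_id: a.status for a in run_phenotyping(cohort, AS_OF, lexicon)}
        assert statuses == {"A": "case_definite", "B": "control", "C": "ineligible"}

    def test_subtype_code_without_poag_falls_through_both_arms(self, lexicon):
        rec = make_record(icd9=("365.23",))
        [a] = run_phenotyping([rec], AS_OF, lexicon)
        assert a.status == "excluded_from_controls"

    def test_empty_cohort_and_duplicate_ids(self, lexicon):
        assert run_phenotyping([], AS_OF, lexicon) == []
        with pytest.raises(ValueError):
            run_phenotyping([make_record(sid="X"), make_record(sid="X")], AS_OF, lexicon)


# --- randomized cohorts with an evidence-level oracle -----------------------

SURGERY_TEXT = "selective laser trabeculoplasty of the right eye"
TEXTS = {
    "none": None,
    "problem_glaucoma": ("problem_list", "Problems: glaucoma; hyperlipidemia"),
    "note_poag": ("clinic_note", "follow-up of POAG, stable"),
    "suspect": ("clinic_note", "patient is a glaucoma suspect"),
    "subtype": ("clinic_note", "uveitic glaucoma, managed by retina"),
    "misspelling": ("clinic_note", "history of glocoma per outside records"),
}
COUNTABLE_TEXT = {"problem_glaucoma", "note_poag"}
VARIANT_TEXT = {"problem_glaucoma", "suspect", "subtype", "misspelling"}


def random_features(rng: random.Random) -> dict:
    return {
        "age": rng.choice([15, 20, 21, 39, 40, 55, 70]),
        "elig_cpt": rng.random() < 0.8,
        "fundus_cpt": rng.random() < 0.4,
        "n_poag_dates": rng.choice([0, 0, 0, 1, 1, 2]),
        "same_day_dup": rng.random() < 0.3,
        "other_glaucoma_code": rng.random() < 0.25,
        "med": rng.random() < 0.5,
        "surgery": rng.random() < 0.3,
        "letter_poag": rng.random() < 0.25,
        "text": rng.choice(list(TEXTS)),
    }


def build_record(sid: str, f: dict):
    cpt = (["99213"] if f["elig_cpt"] else []) + (["92250"] if f["fundus_cpt"] else [])
    icd9 = [("365.11", f"200{d + 5}-01-01") for d in range(f["n_poag_dates"])]
    if f["n_poag_dates"] and f["same_day_dup"]:
        icd9.append(("365.11", icd9[0][1]))
    if f["other_glaucoma_code"]:
        icd9.append(("365.23", "2007-03-03"))
    docs = []
    if f["surgery"]:
        docs.append(("surgical_report", SURGERY_TEXT))
    if f["letter_poag"]:
        docs.append(("ophtho_letter", "Impression: primary open-angle glaucoma, OU"))
    if TEXTS[f["text"]]:
        docs.append(TEXTS[f["text"]])
    return make_record(
        sid=sid, birth_year=AS_OF.year - f["age"], cpt=tuple(cpt), icd9=tuple(icd9),
        meds=("latanoprost",) if f["med"] else (), docs=tuple(docs),
    )


def expected_status(f: dict) -> str:
    """Independent re-reading of the decision rules over the planted evidence."""
    if f["age"] <= 20 or not (f["elig_cpt"] or f["fundus_cpt"]):
        return "ineligible"
    if f["n_poag_dates"] >= 1:
        if f["letter_poag"]:
            return "case_definite"
        if f["n_poag_dates"] >= 2 and f["med"] and f["surgery"]:
            return "case_definite"
        if f["fundus_cpt"] and f["med"] and f["text"] in COUNTABLE_TEXT:
            return "case_potential"
        return "case_indeterminate"
    # "POAG" alone (note_poag) carries no glaucoma spelling variant, so it
    # does not trip the control free-text exclusion
    if f["other_glaucoma_code"] or f["text"] in VARIANT_TEXT:
        return "excluded_from_controls"
    if f["age"] < 40:
        return "excluded_from_controls"
    return "control"


@pytest.mark.parametrize("seed", [11, 22, 33])
def test_agrees_with_evidence_oracle_on_random_cohorts(seed, lexicon):
    rng = random.Random(seed)
    feats = [random_features(rng) for _ in range(200)]
    cohort = [build_record(f"R{i:03d}", f) for i, f in enumerate(feats)]
    assignments = run_phenotyping(cohort, AS_OF, lexicon)
    assert len(assignments) == 200
    for a, f in zip(assignments, feats):
        assert a.status == expected_status(f), (a.subject_id, f, a.status, a.reasons)


def test_statuses_partition_the_cohort(lexicon):
    rng = random.Random(7)
    cohort = [build_record(f"R{i:03d}", random_features(rng)) for i in range(150)]
    assignments = run_phenotyping(cohort, AS_OF, lexicon)
    assert len(assignments) == len(cohort)
    assert len({a.subject_id for a in assignments}) == len(cohort)
    case_tiers = {"case_definite", "case_potential", "case_indeterminate"}
    for a in assignments:
        assert a.status in case_tiers | {"ineligible", "control", "excluded_from_controls"}


def test_adding_poag_code_never_moves_toward_control(lexicon):
    rng = random.Random(13)
    for i in range(60):
        f = random_features(rng)
        rec = build_record(f"R{i:03d}", f)
        [before] = run_phenotyping([rec], AS_OF, lexicon)
        rec.coded_events.append(
            CodedEvent(rec.subject_id, "ICD9", "365.11", dt.date(2012, 12, 1))
        )
        [after] = run_phenotyping([rec], AS_OF, lexicon)
        assert after.status != "control"
        if before.status == "ineligible":
            assert after.status == "ineligible"


def test_removing_all_glaucoma_evidence_restores_control(lexicon):
    rec = make_record(
        birth_year=1950,
        icd9=("365.23",),
        docs=[("clinic_note", "glaucoma mentioned")],
    )
    [a] = run_phenotyping([rec], AS_OF, lexicon)
    assert a.status == "excluded_from_controls"
    rec.coded_events = [e for e in rec.coded_events if not e.code.startswith("365")]
    rec.documents = []
    [a2] = run_phenotyping([rec], AS_OF, lexicon)
    assert a2.status == "control"
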