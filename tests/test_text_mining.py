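import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poagpheno import (
    ClinicalDocument,
    detect_diagnosis_statements,
    extract_cdr,
    find_terms,
    most_recent_cdr,
)
from poagpheno.text_mining import CdrMeasurement, find_case_text_mentions

D = dt.date(2011, 5, 1)


def doc(text, doc_type="clinic_note", doc_id="d1", date=D):
    return ClinicalDocument(doc_id, "P1", doc_type, date, text)


class TestFindTerms:
    def test_spelling_variant_found_case_insensitively(self, lexicon):
        hits = find_terms([doc("Dx: Gloucoma suspect")], lexicon.glaucoma_spelling_variants)
        assert [h.term for h in hits] == ["gloucoma"]

    def test_substring_match_on_abbreviation(self, lexicon):
        hits = find_terms([doc("ophthalmology consult")], lexicon.control_review_terms,
                          whole_word=False)
        assert "ophth" in {h.term for h in hits}

    def test_whole_word_requires_boundaries(self):
        assert find_terms([doc("visionary plan")], ["vision"], whole_word=True) == []
        assert find_terms([doc("vision intact")], ["vision"], whole_word=True) != []

    def test_matches_come_back_in_document_then_offset_order(self):
        docs = [doc("b then a", doc_id="d1"), doc("a then b", doc_id="d2")]
        hits = find_terms(docs, ["a", "b"], whole_word=True)
        assert [(h.document_id, h.term) for h in hits] == [
            ("d1", "b"), ("d1", "a"), ("d2", "a"), ("d2", "b"),
        ]

    @given(st.text(alphabet="abc glaucoma.", max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_whole_word_matches_are_subset_of_substring_matches(self, text):
        terms = ["glaucoma", "a", "ma"]
        strict = {(h.term, h.char_offset) for h in find_terms([doc(text)], terms, True)}
        loose = {(h.term, h.char_offset) for h in find_terms([doc(text)], terms, False)}
        assert strict <= loose


class TestExtractCdr:
    def test_paired_values_with_trailing_laterality(self):
        ms, rep = extract_cdr([doc("cup-to-disc ratio of 0.7 OD and 0.8 OS")])
        assert [(m.eye, m.value) for m in ms] == [("OD", 0.7), ("OS", 0.8)]
        assert rep.n_missing == 0

    def test_pair_without_markers_is_unspecified(self):
        ms, _ = extract_cdr([doc("CDR: 0.95/0.6 today")])
        assert [(m.eye, m.value) for m in ms] == [("unspecified", 0.95), ("unspecified", 0.6)]

    def test_positional_od_os_pair_convention(self):
        ms, _ = extract_cdr([doc("C/D OD/OS: 0.4/0.9")])
        assert [(m.eye, m.value) for m in ms] == [("OD", 0.4), ("OS", 0.9)]

    def test_value_free_mention_recorded_as_miss(self):
        ms, rep = extract_cdr([doc("CDR stable, see drawing from last visit")])
        assert ms == [] and rep.n_missing == 1

    def test_hyphen_space_tolerance_and_axis(self):
        ms, _ = extract_cdr([doc("vertical cup to disk ratio 0.55 O.S.")])
        assert [(m.eye, m.value, m.axis) for m in ms] == [("OS", 0.55, "vertical")]

    def test_value_outside_window_not_captured(self):
        ms, rep = extract_cdr([doc("CDR discussed. " + "x" * 60 + " 0.7 OD")])
        assert ms == [] and rep.n_missing == 1

    def test_source_span_is_verbatim(self):
        text = "Exam: Cup-to-Disc ratio of 0.7 OD noted."
        ms, _ = extract_cdr([doc(text)])
        assert len(ms) == 1 and ms[0].source_span in text

    def test_values_always_within_unit_interval(self):
        with pytest.raises(ValueError):
            CdrMeasurement("P1", "OD", 1.2, D, "cdr 1.2")


class TestMostRecent:
    def m(self, eye, value, date, offset=0, order=0):
        return CdrMeasurement("P1", eye, value, dt.date.fromisoformat(date),
                              "cdr", char_offset=offset, order=order)

    def test_latest_date_wins_per_eye(self):
        latest = most_recent_cdr([
            self.m("OD", 0.5, "2010-01-01"), self.m("OD", 0.7, "2012-06-01"),
        ])
        assert latest["OD"].value == 0.7

    def test_one_sided_input_yields_one_eye(self):
        latest = most_recent_cdr([self.m("OS", 0.6, "2010-01-01")])
        assert set(latest) == {"OS"}
        assert most_recent_cdr([]) == {}

    def test_same_date_tie_broken_by_later_span_matches_bruteforce(self):
        ms = [
            self.m("OD", 0.4, "2010-01-01", offset=10, order=0),
            self.m("OD", 0.6, "2010-01-01", offset=50, order=1),
        ]
        for perm in (ms, ms[::-1]):
            expected = max(perm, key=lambda m: (m.doc_date, m.char_offset, m.order))
            assert most_recent_cdr(perm)["OD"] == expected


class TestDiagnosisStatements:
    def test_poag_impression_in_letter(self, lexicon):
        s = detect_diagnosis_statements(
            [doc("Impression: primary open-angle glaucoma, OU", "ophtho_letter")], lexicon
        )
        assert [x.subtype_label for x in s] == ["POAG"]

    def test_suspect_phrase_is_ambiguous_not_glaucoma(self, lexicon):
        s = detect_diagnosis_statements([doc("patient is a glaucoma suspect")], lexicon)
        assert [x.subtype_label for x in s] == ["ambiguous"]

    def test_other_subtype_detected(self, lexicon):
        s = detect_diagnosis_statements([doc("neovascular glaucoma secondary to PDR")], lexicon)
        assert [x.subtype_label for x in s] == ["neovascular"]

    def test_bare_variant_is_general_glaucoma(self, lexicon):
        s = detect_diagnosis_statements([doc("history of glaucoma, stable")], lexicon)
        assert [x.subtype_label for x in s] == ["general_glaucoma"]

    def test_surgical_reports_not_scanned(self, lexicon):
        s = detect_diagnosis_statements(
            [doc("primary open-angle glaucoma", "surgical_report")], lexicon
        )
        assert s == []


class TestCaseTextMentions:
    def test_problem_list_glaucoma_counts(self, lexicon):
        hits = find_case_text_mentions([doc("Problem list: glaucoma", "problem_list")], lexicon)
        assert hits != []

    @pytest.mark.parametrize(
        "text", ["glaucoma suspect", "advanced glaucoma noted", "neovascular glaucoma"]
    )
    def test_embedded_mentions_never_count(self, text, lexicon):
        assert find_case_text_mentions([doc(text)], lexicon) == []


def test_extraction_is_deterministic(lexicon):
    docs = [doc("CDR 0.7 OD, 0.6 OS"), doc("cup-to-disk 0.5/0.4", doc_id="d2")]
    assert extract_cdr(docs) == extract_cdr(docs)
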