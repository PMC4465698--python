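"""Free-text search primitives and the cup-to-disc-ratio (CDR) extractor.

The extractor targets the surface forms ophthalmologists actually use in
referral letters and clinic notes: the key phrases ``CDR``, ``C/D``,
``cup-to-disc (ratio)`` and ``cup-to-disk (ratio)`` in any hyphen/space
spelling, followed within a bounded character window by one or two decimal
values in [0, 1].  Laterality comes from the nearest ``OD``/``O.D.``/
``right eye`` or ``OS``/``O.S.``/``left eye`` marker, from an ``OD/OS``
positional pair, or is left unspecified.  Values outside [0, 1] and key
phrases with no value in the window are recorded in an extraction report —
the notes really do contain value-free CDR mentions — never silently
dropped.

No general clinical NLP is attempted (no negation detection, no section
segmentation): the published pipeline used none, and the point is that plain
pattern matching already recovers the measurement.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

from .emr_model import ClinicalDocument
from .lexicons import AlgorithmLexicon

__all__ = [
    "TermMatch",
    "CdrMeasurement",
    "DiagnosisStatement",
    "ExtractionReport",
    "find_terms",
    "extract_cdr",
    "most_recent_cdr",
    "detect_diagnosis_statements",
    "find_case_text_mentions",
]

#: characters allowed between a CDR key phrase and its value(s)
CDR_WINDOW = 40

#: characters searched around a value for a laterality marker
_LATERALITY_REACH = 25


@dataclass(frozen=True)
class TermMatch:
    document_id: str
    term: str
    char_offset: int
    doc_date: dt.date


@dataclass(frozen=True)
class CdrMeasurement:
    subject_id: str
    eye: str                      # "OD" | "OS" | "unspecified"
    value: float
    doc_date: dt.date
    source_span: str
    axis: str = "unspecified"     # "horizontal" | "vertical" | "unspecified"
    document_id: str = ""
    char_offset: int = 0          # offset of the value within its document
    order: int = 0                # extraction sequence number (tie-break)

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"CDR value {self.value} outside [0, 1]")
        if self.eye not in ("OD", "OS", "unspecified"):
            raise ValueError(f"bad eye {self.eye!r}")


@dataclass(frozen=True)
class DiagnosisStatement:
    document_id: str
    subtype_label: str            # POAG | uveitic | ... | ambiguous | general_glaucoma
    doc_date: dt.date
    char_offset: int = 0


@dataclass
class ExtractionReport:
    """Key-phrase hits that yielded no usable value."""

    value_free_mentions: list[tuple[str, int]] = field(default_factory=list)  # (doc_id, offset)
    rejected_values: list[tuple[str, int, str]] = field(default_factory=list)  # (doc_id, offset, token)

    @property
    def n_missing(self) -> int:
        return len(self.value_free_mentions)


def _term_pattern(term: str, whole_word: bool) -> re.Pattern[str]:
    pat = re.escape(term)
    if whole_word:
        pat = r"(?<![A-Za-z0-9])" + pat + r"(?![A-Za-z0-9])"
    return re.compile(pat, re.IGNORECASE)


def find_terms(
    documents: list[ClinicalDocument],
    terms: list[str] | tuple[str, ...],
    whole_word: bool = False,
) -> list[TermMatch]:
    """Case-insensitive search for *terms* across *documents*.

    With ``whole_word=True`` a match must be bounded by non-alphanumerics on
    both sides.  Matches are returned in document order then offset order;
    overlapping terms are each reported.
    """
    patterns = [(t, _term_pattern(t, whole_word)) for t in terms]
    out: list[TermMatch] = []
    for doc in documents:
        hits: list[TermMatch] = []
        for term, pat in patterns:
            for m in pat.finditer(doc.text):
                hits.append(TermMatch(doc.document_id, term, m.start(), doc.doc_date))
        hits.sort(key=lambda h: (h.char_offset, h.term))
        out.extend(hits)
    return out


# -- CDR extraction ----------------------------------------------------------

# cdr / c.d.r. / c/d / cup-to-disc [ratio] / cup to disk [ratio], any hyphen
# or space separation, case-insensitive
_CDR_PHRASE = re.compile(
    r"(?<![A-Za-z0-9])(?:"
    r"c\.?d\.?r\.?"
    r"|c\s*/\s*d"
    r"|cup[\s-]*to[\s-]*dis[ck](?:[\s-]*ratios?)?"
    r")(?![A-Za-z0-9])",
    re.IGNORECASE,
)

# a decimal value token: 0.x, .x, 1.0, or a bare 0/1; a sentence-ending
# period may follow, but not a digit or a decimal continuation
_VALUE = re.compile(r"(?<![\d.])(?:[01]?\.\d+|[01](?:\.0+)?)(?!\.?\d)")

_OD = re.compile(r"(?<![A-Za-z])(?:o\.?d\.?|right\s+eye)(?![A-Za-z])", re.IGNORECASE)
_OS = re.compile(r"(?<![A-Za-z])(?:o\.?s\.?|left\s+eye)(?![A-Za-z])", re.IGNORECASE)
_OD_OS_PAIR = re.compile(r"(?<![A-Za-z])o\.?d\.?\s*/\s*o\.?s\.?(?![A-Za-z])", re.IGNORECASE)
_AXIS = re.compile(r"(?<![A-Za-z])(horizontal|vertical|h\s*/\s*v)(?![A-Za-z])", re.IGNORECASE)


def _axis_near(text: str, start: int, end: int) -> str:
    lo, hi = max(0, start - 20), min(len(text), end + 20)
    m = _AXIS.search(text, lo, hi)
    if not m:
        return "unspecified"
    token = m.group(1).lower()
    if token.startswith("h") and "/" in token:
        return "unspecified"  # "H/V" quotient: genuinely ambiguous, leave unresolved
    return token


def _nearest_eye(text: str, vstart: int, vend: int, lo: int, hi: int) -> str:
    # distance between the value span and the marker span; ties prefer the
    # marker following the value ("0.7 OD" is the dominant convention)
    best: tuple[int, int, str] | None = None
    for eye, pat in (("OD", _OD), ("OS", _OS)):
        for m in pat.finditer(text, lo, hi):
            gap = max(0, m.start() - vend, vstart - m.end())
            follows = 0 if m.start() >= vend else 1
            if gap <= _LATERALITY_REACH and (best is None or (gap, follows) < best[:2]):
                best = (gap, follows, eye)
    return best[2] if best else "unspecified"


def extract_cdr(
    documents: list[ClinicalDocument],
    window: int = CDR_WINDOW,
) -> tuple[list[CdrMeasurement], ExtractionReport]:
    """Extract cup-to-disc measurements from free text.

    Returns the accepted measurements (document order, deterministic) and an
    :class:`ExtractionReport` listing value-free key-phrase mentions and
    rejected out-of-range values.
    """
    report = ExtractionReport()
    out: list[CdrMeasurement] = []
    order = 0
    for doc in documents:
        text = doc.text
        claimed: set[int] = set()  # value offsets already consumed by an earlier phrase
        for pm in _CDR_PHRASE.finditer(text):
            win_lo, win_hi = pm.end(), min(len(text), pm.end() + window)
            values = [
                v for v in _VALUE.finditer(text, win_lo, win_hi) if v.start() not in claimed
            ]
            axis = _axis_near(text, pm.start(), pm.end())
            accepted = []
            for v in values:
                x = float(v.group(0))
                if 0.0 <= x <= 1.0:
                    accepted.append((v, x))
                else:  # pragma: no cover - _VALUE only admits [0,1] tokens
                    report.rejected_values.append((doc.document_id, v.start(), v.group(0)))
            if not accepted:
                report.value_free_mentions.append((doc.document_id, pm.start()))
                continue
            # positional OD/OS pair convention: "c/d OD/OS: 0.7/0.6"
            pair_marker = _OD_OS_PAIR.search(text, max(0, pm.start() - 10), win_hi)
            eyes: list[str]
            if pair_marker and len(accepted) == 2:
                eyes = ["OD", "OS"]
            else:
                lo = max(0, pm.start() - _LATERALITY_REACH)
                hi = min(len(text), win_hi + _LATERALITY_REACH)
                eyes = [_nearest_eye(text, v.start(), v.end(), lo, hi) for v, _ in accepted]
            span_end = max(v.end() for v, _ in accepted)
            for (v, x), eye in zip(accepted, eyes):
                claimed.add(v.start())
                out.append(
                    CdrMeasurement(
                        subject_id=doc.subject_id,
                        eye=eye,
                        value=x,
                        doc_date=doc.doc_date,
                        source_span=text[pm.start():span_end],
                        axis=axis,
                        document_id=doc.document_id,
                        char_offset=v.start(),
                        order=order,
                    )
                )
                order += 1
    return out, report


def most_recent_cdr(measurements: list[CdrMeasurement]) -> dict[str, CdrMeasurement]:
    """Latest measurement per eye.

    Ties on date are broken by the latest character position within the
    document, then by extraction order (last wins), so the result is
    deterministic for any input ordering produced by :func:`extract_cdr`.
    """
    latest: dict[str, CdrMeasurement] = {}
    for m in measurements:
        cur = latest.get(m.eye)
        if cur is None or (m.doc_date, m.char_offset, m.order) >= (
            cur.doc_date,
            cur.char_offset,
            cur.order,
        ):
            latest[m.eye] = m
    return latest


# -- diagnosis statements ----------------------------------------------------

_POAG_STMT = re.compile(
    r"(?<![A-Za-z0-9])(?:primary\s+open[\s-]*angle\s+glaucoma|poag)(?![A-Za-z0-9])",
    re.IGNORECASE,
)

_STATEMENT_DOC_TYPES = ("ophtho_letter", "clinic_note")


def _phrase_spans(text: str, phrases: tuple[str, ...]) -> list[tuple[int, int]]:
    spans = []
    for p in phrases:
        for m in _term_pattern(p, whole_word=True).finditer(text):
            spans.append((m.start(), m.end()))
    return spans


def detect_diagnosis_statements(
    documents: list[ClinicalDocument],
    lexicon: AlgorithmLexicon,
) -> list[DiagnosisStatement]:
    """Find written glaucoma-subtype diagnosis statements.

    Scans ophthalmology letters and clinic notes for: POAG statements
    ("primary open-angle glaucoma" or standalone "POAG"), the configured
    other-subtype phrases, the ambiguity phrases ("advanced glaucoma",
    "ocular hypertension", "glaucoma suspect"), and — for glaucoma spelling
    variants not embedded in any of the above — a ``general_glaucoma``
    statement.  A document may yield several statements.
    """
    out: list[DiagnosisStatement] = []
    for doc in documents:
        if doc.doc_type not in _STATEMENT_DOC_TYPES:
            continue
        text = doc.text
        hits: list[tuple[int, int, str]] = []
        for m in _POAG_STMT.finditer(text):
            hits.append((m.start(), m.end(), "POAG"))
        for label, phrases in lexicon.other_subtype_labels:
            for s, e in _phrase_spans(text, phrases):
                hits.append((s, e, label))
        for s, e in _phrase_spans(text, lexicon.ambiguity_phrases):
            hits.append((s, e, "ambiguous"))
        qualified = [(s, e) for s, e, _ in hits]
        for s, e in _phrase_spans(text, lexicon.glaucoma_spelling_variants):
            if not any(qs <= s and e <= qe for qs, qe in qualified):
                hits.append((s, e, "general_glaucoma"))
        hits.sort(key=lambda h: (h[0], h[1]))
        out.extend(
            DiagnosisStatement(doc.document_id, label, doc.doc_date, char_offset=s)
            for s, _e, label in hits
        )
    return out


def find_case_text_mentions(
    documents: list[ClinicalDocument],
    lexicon: AlgorithmLexicon,
) -> list[TermMatch]:
    """Mentions of "POAG" or "glaucoma" in clinic notes / problem lists that
    may count as case evidence.

    Mentions embedded in an ambiguity phrase ("advanced glaucoma", "ocular
    hypertension", "glaucoma suspect") or in another-subtype diagnosis
    ("neovascular glaucoma", ...) never count toward POAG case status and
    are excluded.
    """
    docs = [d for d in documents if d.doc_type in ("clinic_note", "problem_list")]
    out: list[TermMatch] = []
    for doc in docs:
        amb = _phrase_spans(doc.text, lexicon.ambiguity_phrases)
        for _label, phrases in lexicon.other_subtype_labels:
            amb.extend(_phrase_spans(doc.text, phrases))
        for pat, name in ((_POAG_STMT, "poag"),
                          (_term_pattern("glaucoma", whole_word=True), "glaucoma")):
            for m in pat.finditer(doc.text):
                if any(s <= m.start() and m.end() <= e for s, e in amb):
                    continue
                out.append(TermMatch(doc.document_id, name, m.start(), doc.doc_date))
    return out
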