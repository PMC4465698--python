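import datetime as dt

import pytest

from poagpheno import (
    ClinicalDocument,
    CodedEvent,
    Demographics,
    MedicationMention,
    PatientRecord,
    default_lexicon,
)

AS_OF = dt.date(2013, 3, 20)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_record(
    sid="P1",
    birth_year=1950,
    sex="female",
    cpt=("92014",),
    icd9=(),
    meds=(),
    docs=(),
):
    """Compact record builder: icd9/cpt as (code, iso-date) pairs or bare codes."""

    def ev(system, item, default_date):
        if isinstance(item, tuple):
            code, date = item
            return CodedEvent(sid, system, code, dt.date.fromisoformat(date))
        return CodedEvent(sid, system, item, default_date)

    events = [ev("CPT", c, dt.date(2010, 1, 1)) for c in cpt]
    events += [ev("ICD9", c, dt.date(2009, 6, 1)) for c in icd9]
    medications = [
        MedicationMention(sid, name, dt.date(2010, 2, 1)) for name in meds
    ]
    documents = [
        ClinicalDocument(f"{sid}-d{i}", sid, doc_type, dt.date(2011, 3, 1), text)
        for i, (doc_type, text) in enumerate(docs)
    ]
    return PatientRecord(
        demographics=Demographics(sid, birth_year, sex, "African American"),
        coded_events=events,
        medications=medications,
        documents=documents,
    )
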