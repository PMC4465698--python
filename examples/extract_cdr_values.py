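"""Extract cup-to-disc ratios (CDR) from free-text clinic notes.

The extractor finds key phrases (CDR, C/D, cup-to-disc/disk ratio in any
hyphenation), reads one or two decimal values from a bounded window after
the phrase, and assigns laterality from OD/OS markers.  Value-free mentions
are tallied rather than dropped — real records contain them.  The
most-recent measurement per eye is the one a study would carry forward.
"""

import datetime as dt

from poagpheno import ClinicalDocument, extract_cdr, most_recent_cdr

notes = [
    ClinicalDocument("n1", "P1", "clinic_note", dt.date(2010, 3, 1),
                     "Exam today. Cup-to-disc ratio of 0.5 OD and 0.6 OS."),
    ClinicalDocument("n2", "P1", "ophtho_letter", dt.date(2012, 7, 9),
                     "Fundus: C/D OD/OS: 0.7/0.8. Maculae flat."),
    ClinicalDocument("n3", "P1", "clinic_note", dt.date(2013, 1, 2),
                     "CDR stable, see prior drawing."),
]

measurements, report = extract_cdr(notes)
print("all extracted measurements:")
for m in measurements:
    print(f"  {m.doc_date}  {m.eye:3s} {m.value:.2f}   from {m.source_span!r}")
print(f"value-free CDR mentions: {report.n_missing}")

latest = most_recent_cdr(measurements)
for eye in ("OD", "OS"):
    m = latest[eye]
    print(f"most recent {eye}: {m.value:.2f} on {m.doc_date}")
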