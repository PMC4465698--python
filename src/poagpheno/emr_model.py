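"""Domain types for longitudinal, de-identified EMR data and cohort-directory I/O.

A cohort lives in one directory of plain-text files:

* ``demographics.csv``  — subject_id, birth_year, sex, race_ethnicity
* ``coded_events.csv``  — subject_id, code_system, code, event_date, source_document_id
* ``medications.csv``   — subject_id, drug_name, mention_date
* ``measurements.csv``  — subject_id, kind, value, measure_date
* ``documents.jsonl``   — one JSON object per clinical document
                          (document_id, subject_id, doc_type, doc_date, text)

Dates are ISO-8601 calendar dates.  Only the birth *year* is modelled — the
source records are de-identified to year resolution — so ages are integer
year differences.  Rows that cannot be parsed are quarantined into a load
report rather than silently dropped.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Demographics",
    "CodedEvent",
    "MedicationMention",
    "Measurement",
    "ClinicalDocument",
    "PatientRecord",
    "LoadReport",
    "QuarantinedRow",
    "load_cohort",
    "write_cohort",
    "age_at",
]

SEXES = {"female", "male", "unknown"}
CODE_SYSTEMS = {"ICD9", "CPT"}
MEASUREMENT_KINDS = {
    "sbp",
    "dbp",
    "height",
    "weight",
    "bmi",
    "total_cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
}
DOC_TYPES = {"ophtho_letter", "surgical_report", "problem_list", "clinic_note"}

# loose plausibility bounds per measurement kind; violations warn, never fail
_PLAUSIBLE = {
    "sbp": (50, 300),
    "dbp": (20, 200),
    "height": (50, 250),       # cm
    "weight": (20, 400),       # kg
    "bmi": (10, 100),
    "total_cholesterol": (50, 600),
    "hdl": (5, 200),
    "ldl": (10, 400),
    "triglycerides": (10, 3000),
}

_BIRTH_YEAR_MIN = 1880


@dataclass(frozen=True)
class Demographics:
    subject_id: str
    birth_year: int
    sex: str = "unknown"
    race_ethnicity: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        year_now = dt.date.today().year
        if not (_BIRTH_YEAR_MIN <= self.birth_year <= year_now):
            raise ValueError(
                f"implausible birth_year {self.birth_year} "
                f"(expected {_BIRTH_YEAR_MIN}..{year_now})"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")


@dataclass(frozen=True)
class CodedEvent:
    subject_id: str
    code_system: str
    code: str
    event_date: dt.date
    source_document_id: str | None = None

    def __post_init__(self) -> None:
        if self.code_system not in CODE_SYSTEMS:
            raise ValueError(f"code_system must be ICD9 or CPT, got {self.code_system!r}")
        if self.code_system == "ICD9":
            stripped = self.code.replace(".", "", 1)
            if not stripped.isdigit() or self.code.startswith(".") or self.code.endswith("."):
                raise ValueError(f"malformed ICD-9 code {self.code!r}")
        else:
            if not (len(self.code) == 5 and self.code.isdigit()):
                raise ValueError(f"malformed CPT code {self.code!r} (expected 5 digits)")


@dataclass(frozen=True)
class MedicationMention:
    subject_id: str
    drug_name: str
    mention_date: dt.date

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValueError("drug_name must be non-empty")
        object.__setattr__(self, "drug_name", self.drug_name.lower())


@dataclass(frozen=True)
class Measurement:
    subject_id: str
    kind: str
    value: float
    measure_date: dt.date

    def __post_init__(self) -> None:
        if self.kind not in MEASUREMENT_KINDS:
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if not self.value > 0:
            raise ValueError(f"measurement value must be > 0, got {self.value}")


@dataclass(frozen=True)
class ClinicalDocument:
    document_id: str
    subject_id: str
    doc_type: str
    doc_date: dt.date
    text: str = ""

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"doc_type must be one of {sorted(DOC_TYPES)}, got {self.doc_type!r}")


@dataclass
class PatientRecord:
    """One subject's demographics plus all dated structured and free-text data."""

    demographics: Demographics
    coded_events: list[CodedEvent] = field(default_factory=list)
    medications: list[MedicationMention] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)
    documents: list[ClinicalDocument] = field(default_factory=list)

    @property
    def subject_id(self) -> str:
        return self.demographics.subject_id

    def validate(self) -> None:
        sid = self.subject_id
        for group in (self.coded_events, self.medications, self.measurements, self.documents):
            for item in group:
                if item.subject_id != sid:
                    raise ValueError(
                        f"child subject_id {item.subject_id!r} != record subject_id {sid!r}"
                    )


@dataclass(frozen=True)
class QuarantinedRow:
    source_file: str
    row_number: int
    reason: str
    raw: str


@dataclass
class LoadReport:
    """Rows rejected during cohort load, with the reason each was rejected."""

    quarantined: list[QuarantinedRow] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)

    def add(self, source_file: str, row_number: int, reason: str, raw: object) -> None:
        self.quarantined.append(QuarantinedRow(source_file, row_number, reason, str(raw)))

    def write(self, path: str | Path) -> None:
        lines = [f"quarantined rows: {self.n_quarantined}"]
        for q in self.quarantined:
            lines.append(f"{q.source_file}:{q.row_number}\t{q.reason}\t{q.raw}")
        if self.warnings:
            lines.append(f"warnings: {len(self.warnings)}")
            lines.extend(self.warnings)
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def age_at(demographics: Demographics, on_date: dt.date) -> int:
    """Integer age in years on *on_date*, computed from the birth year alone."""
    age = on_date.year - demographics.birth_year
    if age < 0:
        raise ValueError(
            f"date {on_date.isoformat()} precedes birth year {demographics.birth_year}"
        )
    return age


def _parse_date(value: object) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value).strip())


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def load_cohort(path: str | Path) -> tuple[list[PatientRecord], LoadReport]:
    """Load a cohort directory into typed :class:`PatientRecord` objects.

    Returns the records (ordered by subject_id as listed in demographics.csv)
    and a :class:`LoadReport` of quarantined rows.  A missing required file is
    fatal; a malformed row quarantines that row only.
    """
    root = Path(path)
    required = [
        "demographics.csv",
        "coded_events.csv",
        "medications.csv",
        "measurements.csv",
        "documents.jsonl",
    ]
    for name in required:
        if not (root / name).exists():
            raise FileNotFoundError(f"cohort directory {root} is missing required file {name}")

    report = LoadReport()
    records: dict[str, PatientRecord] = {}

    demo = _read_csv(root / "demographics.csv")
    for i, row in demo.iterrows():
        rownum = int(i) + 2  # 1-based, after header
        try:
            d = Demographics(
                subject_id=row["subject_id"],
                birth_year=int(row["birth_year"]),
                sex=row.get("sex", "unknown") or "unknown",
                race_ethnicity=row.get("race_ethnicity", ""),
            )
        except (ValueError, KeyError) as exc:
            report.add("demographics.csv", rownum, str(exc), row.to_dict())
            continue
        if d.subject_id in records:
            raise ValueError(f"duplicate subject_id {d.subject_id!r} in demographics.csv")
        records[d.subject_id] = PatientRecord(demographics=d)

    def _attach(filename: str, build) -> None:
        df = _read_csv(root / filename)
        for i, row in df.iterrows():
            rownum = int(i) + 2
            try:
                sid, item = build(row)
            except (ValueError, KeyError) as exc:
                report.add(filename, rownum, str(exc), row.to_dict())
                continue
            rec = records.get(sid)
            if rec is None:
                report.add(filename, rownum, f"unknown subject_id {sid!r}", row.to_dict())
                continue
            if isinstance(item, CodedEvent):
                rec.coded_events.append(item)
            elif isinstance(item, MedicationMention):
                rec.medications.append(item)
            else:
                rec.measurements.append(item)

    _attach(
        "coded_events.csv",
        lambda row: (
            row["subject_id"],
            CodedEvent(
                subject_id=row["subject_id"],
                code_system=row["code_system"],
                code=row["code"],
                event_date=_parse_date(row["event_date"]),
                source_document_id=row.get("source_document_id") or None,
            ),
        ),
    )
    _attach(
        "medications.csv",
        lambda row: (
            row["subject_id"],
            MedicationMention(
                subject_id=row["subject_id"],
                drug_name=row["drug_name"],
                mention_date=_parse_date(row["mention_date"]),
            ),
        ),
    )
    _attach(
        "measurements.csv",
        lambda row: (
            row["subject_id"],
            Measurement(
                subject_id=row["subject_id"],
                kind=row["kind"],
                value=float(row["value"]),
                measure_date=_parse_date(row["measure_date"]),
            ),
        ),
    )

    with open(root / "documents.jsonl", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc = ClinicalDocument(
                    document_id=obj["document_id"],
                    subject_id=obj["subject_id"],
                    doc_type=obj["doc_type"],
                    doc_date=_parse_date(obj["doc_date"]),
                    text=obj.get("text", ""),
                )
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                report.add("documents.jsonl", lineno, str(exc), line.strip())
                continue
            rec = records.get(doc.subject_id)
            if rec is None:
                report.add("documents.jsonl", lineno, f"unknown subject_id {doc.subject_id!r}", line.strip())
                continue
            rec.documents.append(doc)

    for rec in records.values():
        for m in rec.measurements:
            lo, hi = _PLAUSIBLE[m.kind]
            if not (lo <= m.value <= hi):
                report.warnings.append(
                    f"implausible {m.kind} value {m.value} for subject {m.subject_id}"
                )

    return list(records.values()), report


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records back out in the cohort directory dialect (UTF-8, headers)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    records = list(records)

    pd.DataFrame(
        [
            {
                "subject_id": r.demographics.subject_id,
                "birth_year": r.demographics.birth_year,
                "sex": r.demographics.sex,
                "race_ethnicity": r.demographics.race_ethnicity,
            }
            for r in records
        ],
        columns=["subject_id", "birth_year", "sex", "race_ethnicity"],
    ).to_csv(root / "demographics.csv", index=False)

    pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "code_system": e.code_system,
                "code": e.code,
                "event_date": e.event_date.isoformat(),
                "source_document_id": e.source_document_id or "",
            }
            for r in records
            for e in r.coded_events
        ],
        columns=["subject_id", "code_system", "code", "event_date", "source_document_id"],
    ).to_csv(root / "coded_events.csv", index=False)

    pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "drug_name": m.drug_name,
                "mention_date": m.mention_date.isoformat(),
            }
            for r in records
            for m in r.medications
        ],
        columns=["subject_id", "drug_name", "mention_date"],
    ).to_csv(root / "medications.csv", index=False)

    pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "kind": m.kind,
                "value": m.value,
                "measure_date": m.measure_date.isoformat(),
            }
            for r in records
            for m in r.measurements
        ],
        columns=["subject_id", "kind", "value", "measure_date"],
    ).to_csv(root / "measurements.csv", index=False)

    with open(root / "documents.jsonl", "w", encoding="utf-8") as fh:
        for r in records:
            for d in r.documents:
                fh.write(
                    json.dumps(
                        {
                            "document_id": d.document_id,
                            "subject_id": d.subject_id,
                            "doc_type": d.doc_type,
                            "doc_date": d.doc_date.isoformat(),
                            "text": d.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
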