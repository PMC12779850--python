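"""Patient records and corpus I/O.

A patient is an ordered list of dated free-text discharge reports. Corpora are
stored as JSON-Lines, one patient per line, with ISO-8601 (yyyy-mm-dd) dates::

    {"schema": 1, "patient_id": "P001", "gold_label": 1,
     "reports": [{"id": "r1", "date": "2018-08-11", "text": "..."}]}

Only report dates anchor time: intra-note temporal expressions ("hace dos
años") are deliberately not interpreted.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

SCHEMA_VERSION = 1


class CorpusFormatError(ValueError):
    """Raised when a corpus file contains malformed records.

    The message lists every offending line number together with the patient
    and report identifiers involved.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("corpus format errors:\n" + "\n".join(self.problems))


@dataclass
class DischargeReport:
    """One dated free-text discharge note."""

    report_id: str
    date: datetime.date
    text: str
    #: optional cached segmentation (list of nlp.Section); populated lazily
    sections: Optional[list] = None

    def __post_init__(self) -> None:
        if not isinstance(self.date, datetime.date):
            raise TypeError(f"report {self.report_id!r}: date must be a datetime.date")


@dataclass
class PatientHistory:
    """All discharge reports of one patient, optionally with a gold label."""

    patient_id: str
    reports: list[DischargeReport] = field(default_factory=list)
    gold_label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gold_label not in (None, 1, 0, -1):
            raise ValueError(f"gold_label must be one of 1/0/-1, got {self.gold_label!r}")
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"patient {self.patient_id!r}: duplicate report ids {dupes}")


def build_timeline(history: PatientHistory) -> PatientHistory:
    """Return a copy with reports sorted ascending by date.

    Same-date reports are ordered by ``report_id`` (lexicographic) so the
    timeline is deterministic under shuffled input. Idempotent.
    """
    ordered = sorted(history.reports, key=lambda r: (r.date, r.report_id))
    return replace(history, reports=ordered)


def days_between(origin: datetime.date, target: datetime.date) -> int:
    """Exact signed calendar-day difference ``target - origin``."""
    return (target - origin).days


def _parse_patient(line: str, lineno: int, problems: list[str]) -> Optional[PatientHistory]:
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        problems.append(f"line {lineno}: invalid JSON ({exc.msg})")
        return None
    if not isinstance(obj, dict) or "patient_id" not in obj:
        problems.append(f"line {lineno}: record is not a patient object with 'patient_id'")
        return None
    pid = obj["patient_id"]
    reports: list[DischargeReport] = []
    seen_ids: set[str] = set()
    ok = True
    for rec in obj.get("reports", []):
        rid = rec.get("id", "?")
        try:
            date = datetime.date.fromisoformat(rec["date"])
        except (KeyError, TypeError, ValueError):
            problems.append(
                f"line {lineno}: patient {pid!r} report {rid!r}: "
                f"unparseable date {rec.get('date')!r}"
            )
            ok = False
            continue
        if rid in seen_ids:
            problems.append(f"line {lineno}: patient {pid!r}: duplicate report id {rid!r}")
            ok = False
            continue
        seen_ids.add(rid)
        reports.append(DischargeReport(report_id=rid, date=date, text=rec.get("text", "")))
    if not ok:
        return None
    gold = obj.get("gold_label")
    if gold not in (None, 1, 0, -1):
        problems.append(f"line {lineno}: patient {pid!r}: invalid gold_label {gold!r}")
        return None
    return PatientHistory(patient_id=pid, reports=reports, gold_label=gold)


def load_corpus(path: str | Path) -> list[PatientHistory]:
    """Load a JSONL patient corpus.

    Raises :class:`CorpusFormatError` listing every malformed line; a corpus
    loads either completely or not at all.
    """
    problems: list[str] = []
    patients: list[PatientHistory] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            patient = _parse_patient(line, lineno, problems)
            if patient is not None:
                patients.append(patient)
    if problems:
        raise CorpusFormatError(problems)
    return patients


def save_corpus(patients: Iterable[PatientHistory], path: str | Path) -> None:
    """Write patients as JSONL (schema 1, ISO dates, text verbatim)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in patients:
            obj = {
                "schema": SCHEMA_VERSION,
                "patient_id": p.patient_id,
                "gold_label": p.gold_label,
                "reports": [
                    {"id": r.report_id, "date": r.date.isoformat(), "text": r.text}
                    for r in p.reports
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
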