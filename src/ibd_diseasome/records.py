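"""Long-format encounter records and their CSV serialization.

One row per dated diagnosis/contact event: the universal input format for
every downstream stage (cohort extraction, frequency tables, co-occurrence
networks).
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ENCOUNTER_TYPES",
    "ICD_CODE_PATTERN",
    "EncounterRecord",
    "RecordParseError",
    "read_records",
    "write_records",
]

#: Accepted administrative encounter sources.
ENCOUNTER_TYPES = ("hospitalization", "physician_claim", "ambulatory")

#: ICD-10-style code: chapter letter, two digits, optional 1-2 digit suffix.
ICD_CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")

_CSV_HEADER = ["patient_id", "date", "icd_code", "encounter_type"]


class RecordParseError(ValueError):
    """Raised when an encounter CSV row cannot be parsed; names the line."""


@dataclass(frozen=True, order=True)
class EncounterRecord:
    """A single dated, coded healthcare contact for one patient."""

    patient_id: str
    date: dt.date
    icd_code: str
    encounter_type: str

    def __post_init__(self) -> None:
        if not ICD_CODE_PATTERN.match(self.icd_code):
            raise ValueError(f"invalid ICD code {self.icd_code!r}")
        if self.encounter_type not in ENCOUNTER_TYPES:
            raise ValueError(f"invalid encounter type {self.encounter_type!r}")


def write_records(records: Iterable[EncounterRecord], path: str | Path) -> None:
    """Write records as CSV with header ``patient_id,date,icd_code,encounter_type``.

    Dates are ISO-8601; the round trip through :func:`read_records` is lossless.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for rec in records:
            writer.writerow(
                [rec.patient_id, rec.date.isoformat(), rec.icd_code, rec.encounter_type]
            )


def read_records(path: str | Path) -> list[EncounterRecord]:
    """Read an encounter CSV written by :func:`write_records`.

    Raises
    ------
    RecordParseError
        On a malformed row; the message names the offending line number.
    """
    records: list[EncounterRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_HEADER:
            raise RecordParseError(f"line 1: expected header {_CSV_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise RecordParseError(f"line {lineno}: expected 4 fields, got {len(row)}")
            pid, date_s, code, etype = row
            try:
                date = dt.date.fromisoformat(date_s)
            except ValueError as exc:
                raise RecordParseError(f"line {lineno}: bad date {date_s!r}") from exc
            try:
                records.append(EncounterRecord(pid, date, code, etype))
            except ValueError as exc:
                raise RecordParseError(f"line {lineno}: {exc}") from exc
    return records
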