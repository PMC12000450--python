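"""Administrative case definition and cohort assembly.

A patient is an IBD case if, inside some two-year (730-day) window, they
accumulate at least 2 hospitalizations OR 4 physician claims OR 2
ambulatory-care contacts carrying an IBD diagnostic code. Each clause is
evaluated independently with a sliding window anchored at each IBD-coded
encounter date; the window is the closed span of ``window_days`` calendar
days starting at the anchor.

Disease subtype is a documented stand-in for the registry's proprietary
scoring: strict majority of IBD-coded encounters K50.x -> CD, K51.x -> UC,
ties or no majority -> IBDU.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import EncounterRecord

__all__ = [
    "CaseDefinition",
    "CohortLabel",
    "age_group",
    "assign_subtype",
    "build_cohort",
    "classify_patient",
    "read_cohort",
    "write_cohort",
]

AGE_GROUPS = ("<18", "18-64", ">64")


@dataclass(frozen=True)
class CaseDefinition:
    """Thresholds of the two-year administrative case definition."""

    window_days: int = 730
    min_hospitalizations: int = 2
    min_physician_claims: int = 4
    min_ambulatory_contacts: int = 2
    #: code prefixes counting as IBD-coded; extend with ("555", "556") where
    #: legacy ICD-9 contacts are pooled in.
    ibd_prefixes: tuple[str, ...] = ("K50", "K51")

    def __post_init__(self) -> None:
        for name in (
            "window_days",
            "min_hospitalizations",
            "min_physician_claims",
            "min_ambulatory_contacts",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class CohortLabel:
    """Per-patient cohort assignment with demographic strata."""

    patient_id: str
    label: str  # CD | UC | IBDU | excluded
    sex: str | None = None
    age_at_first_encounter: float | None = None
    age_group: str | None = None


def _is_ibd_coded(record: EncounterRecord, defn: CaseDefinition) -> bool:
    return record.icd_code.startswith(defn.ibd_prefixes)


def _clause_satisfied(dates: Sequence[dt.date], threshold: int, window_days: int) -> bool:
    """True if some window of ``window_days`` days anchored at an encounter
    holds >= threshold encounters (window = [anchor, anchor + window_days - 1])."""
    dates = sorted(dates)
    n = len(dates)
    if n < threshold:
        return False
    j = 0
    for i in range(n):
        limit = dates[i] + dt.timedelta(days=window_days - 1)
        if j < i:
            j = i
        while j < n and dates[j] <= limit:
            j += 1
        if j - i >= threshold:
            return True
    return False


def classify_patient(
    records: Iterable[EncounterRecord], defn: CaseDefinition | None = None
) -> str:
    """Classify one patient's records as ``"case"`` or ``"excluded"``.

    Only IBD-coded encounters count; each of the three clauses
    (hospitalizations, physician claims, ambulatory contacts) suffices on
    its own. An empty record list is simply excluded.
    """
    defn = defn or CaseDefinition()
    dates_by_type: dict[str, list[dt.date]] = {
        "hospitalization": [],
        "physician_claim": [],
        "ambulatory": [],
    }
    for rec in records:
        if _is_ibd_coded(rec, defn):
            dates_by_type[rec.encounter_type].append(rec.date)
    thresholds = {
        "hospitalization": defn.min_hospitalizations,
        "physician_claim": defn.min_physician_claims,
        "ambulatory": defn.min_ambulatory_contacts,
    }
    for etype, dates in dates_by_type.items():
        if _clause_satisfied(dates, thresholds[etype], defn.window_days):
            return "case"
    return "excluded"


def assign_subtype(
    records: Iterable[EncounterRecord], defn: CaseDefinition | None = None
) -> str:
    """CD/UC/IBDU by strict majority of IBD-coded encounter counts.

    The registry's original subtype scoring is unpublished; this majority
    rule over raw encounter counts is the package's documented stand-in
    (ties and mixed streams without a majority -> IBDU).
    """
    defn = defn or CaseDefinition()
    cd = uc = 0
    for rec in records:
        if rec.icd_code.startswith(("K50", "555")):
            cd += 1
        elif rec.icd_code.startswith(("K51", "556")):
            uc += 1
    if cd > uc:
        return "CD"
    if uc > cd:
        return "UC"
    return "IBDU"


def age_group(age_years: float) -> str:
    """Stratum for an age: ``<18``, ``18-64`` (inclusive) or ``>64``."""
    if age_years < 0:
        raise ValueError(f"age must be >= 0, got {age_years}")
    if age_years < 18:
        return "<18"
    if age_years <= 64:
        return "18-64"
    return ">64"


def _age_at(birth: dt.date, on: dt.date) -> float:
    return (on - birth).days / 365.25


def build_cohort(
    records: Iterable[EncounterRecord],
    defn: CaseDefinition | None = None,
    sex: Mapping[str, str] | None = None,
    birth_date: Mapping[str, dt.date] | None = None,
) -> list[CohortLabel]:
    """Apply the case definition to every patient in a record stream.

    Age at first encounter is computed from the supplied birth dates at the
    patient's earliest record and floored to whole years for stratum
    assignment. Patients are returned in patient-id order.
    """
    defn = defn or CaseDefinition()
    by_patient: dict[str, list[EncounterRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    labels: list[CohortLabel] = []
    for pid in sorted(by_patient):
        recs = sorted(by_patient[pid], key=lambda r: (r.date, r.icd_code))
        status = classify_patient(recs, defn)
        label = assign_subtype(recs, defn) if status == "case" else "excluded"
        age = grp = None
        if birth_date and pid in birth_date:
            age = _age_at(birth_date[pid], recs[0].date)
            grp = age_group(float(int(age)))
        labels.append(
            CohortLabel(
                patient_id=pid,
                label=label,
                sex=sex.get(pid) if sex else None,
                age_at_first_encounter=age,
                age_group=grp,
            )
        )
    return labels


_COHORT_HEADER = ["patient_id", "label", "sex", "age", "age_group"]


def write_cohort(cohort: Iterable[CohortLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_HEADER)
        for c in cohort:
            writer.writerow(
                [
                    c.patient_id,
                    c.label,
                    c.sex or "",
                    "" if c.age_at_first_encounter is None else f"{c.age_at_first_encounter:.3f}",
                    c.age_group or "",
                ]
            )


def read_cohort(path: str | Path) -> list[CohortLabel]:
    out: list[CohortLabel] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                CohortLabel(
                    patient_id=row["patient_id"],
                    label=row["label"],
                    sex=row["sex"] or None,
                    age_at_first_encounter=float(row["age"]) if row["age"] else None,
                    age_group=row["age_group"] or None,
                )
            )
    return out
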