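"""Descriptive frequency layer: counts, 3-decimal percents, chi-square
comparisons, medians/IQRs, healthcare-utilization rates and organ-system
frequency tables.

Conventions match the tabulation style of administrative IBD registry
reports: percents are round-half-even at 3 decimals; binary CD-vs-UC
comparisons use the Pearson chi-square on the 2x2 table *with* Yates
continuity correction (the correction is what reproduces published
p-values from their printed counts); no multiple-testing adjustment is
applied, deliberately — downstream consumers must interpret the p-value
columns accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import CohortLabel
from .domains import IBD_INDEX_DOMAIN, UNMAPPED, DomainMap, default_domain_map
from .records import EncounterRecord

__all__ = [
    "FrequencyRow",
    "chi_square_2x2",
    "frequency_table",
    "frequency_table_to_dataframe",
    "map_code_to_domain",
    "median_iqr",
    "percent",
    "utilization_rate",
]

_DISEASES = ("CD", "UC", "IBDU")


def percent(numerator: int, denominator: int) -> float:
    """100*n/d rounded half-even to 3 decimals (exact decimal arithmetic)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator > denominator:
        raise ValueError("numerator must be <= denominator")
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.001"), rounding=ROUND_HALF_EVEN
    )
    return float(q)


def chi_square_2x2(
    a: int, n1: int, b: int, n2: int, yates: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on [(a, n1-a), (b, n2-b)], df=1, two-sided.

    Yates continuity correction is on by default. An expected cell below 1
    triggers a warning but the result is still returned.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both margins must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("counts must satisfy 0 <= a <= n1 and 0 <= b <= n2")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        warnings.warn("chi-square 2x2: expected cell count below 1", stacklevel=2)
    if (table.sum(axis=0) == 0).any():
        # a zero column makes the statistic degenerate: identical proportions
        return 0.0, 1.0
    res = chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (linear interpolation percentiles)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of an empty sequence")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1)


def utilization_rate(event_count: int, patient_years: float) -> float:
    """Events per patient-year."""
    if patient_years <= 0:
        raise ValueError("patient_years must be > 0")
    return event_count / patient_years


def map_code_to_domain(code: str, domain_map: DomainMap | None = None) -> str:
    """Organ-system domain of a code under an ordered :class:`DomainMap`."""
    return (domain_map or default_domain_map()).map_code(code)


@dataclass(frozen=True)
class FrequencyRow:
    """One organ-system (or code-group) row of a frequency table."""

    row_label: str
    count_CD: int
    count_UC: int
    count_IBDU: int
    count_total: int
    pct_CD: float
    pct_UC: float
    pct_IBDU: float
    pct_total: float
    p_UC_vs_CD: float


def _row(
    label: str,
    patients_by_disease: Mapping[str, set],
    denominators: Mapping[str, int],
) -> FrequencyRow:
    counts = {d: len(patients_by_disease.get(d, set())) for d in _DISEASES}
    total = sum(counts.values())
    denom_total = sum(denominators[d] for d in _DISEASES)
    _, p = chi_square_2x2(
        counts["CD"], denominators["CD"], counts["UC"], denominators["UC"]
    )
    return FrequencyRow(
        row_label=label,
        count_CD=counts["CD"],
        count_UC=counts["UC"],
        count_IBDU=counts["IBDU"],
        count_total=total,
        pct_CD=percent(counts["CD"], denominators["CD"]),
        pct_UC=percent(counts["UC"], denominators["UC"]),
        pct_IBDU=percent(counts["IBDU"], denominators["IBDU"]),
        pct_total=percent(total, denom_total),
        p_UC_vs_CD=p,
    )


def frequency_table(
    records: Iterable[EncounterRecord],
    cohort: Iterable[CohortLabel],
    grouping: DomainMap | Sequence[str] | None = None,
) -> list[FrequencyRow]:
    """Per-group patient counts and CD-vs-UC comparisons.

    ``grouping`` is either a :class:`DomainMap` (one row per organ-system
    domain, sorted by descending total frequency) or an explicit list of
    codes (one row per code). A patient counts once per group regardless of
    code multiplicity; denominators are the per-disease cohort sizes; IBD
    index codes and unmapped codes never count as manifestations. A final
    "Number of patients with any EIM & AID" row summarizes patients with at
    least one qualifying code.
    """
    label_of = {c.patient_id: c.label for c in cohort if c.label in _DISEASES}
    denominators = {
        d: sum(1 for l in label_of.values() if l == d) for d in _DISEASES
    }
    for d in _DISEASES:
        if denominators[d] == 0:
            raise ValueError(f"cohort contains no {d} patients")

    by_code = isinstance(grouping, (list, tuple))
    dmap = grouping if isinstance(grouping, DomainMap) else default_domain_map()

    groups: dict[str, dict[str, set]] = {}
    any_eim: dict[str, set] = {d: set() for d in _DISEASES}
    wanted = set(grouping) if by_code else None
    for rec in records:
        disease = label_of.get(rec.patient_id)
        if disease is None:
            continue
        domain = dmap.map_code(rec.icd_code)
        if domain in (IBD_INDEX_DOMAIN, UNMAPPED):
            continue
        key = rec.icd_code if by_code else domain
        if by_code and key not in wanted:
            continue
        groups.setdefault(key, {d: set() for d in _DISEASES})[disease].add(
            rec.patient_id
        )
        any_eim[disease].add(rec.patient_id)

    if by_code:
        row_labels = list(grouping)
    else:
        row_labels = dmap.domain_names()
    empty = {d: set() for d in _DISEASES}
    rows = [_row(lbl, groups.get(lbl, empty), denominators) for lbl in row_labels]
    if not by_code:
        rows.sort(key=lambda r: (-r.count_total, r.row_label))
    rows.append(_row("Number of patients with any EIM & AID", any_eim, denominators))
    return rows


def frequency_table_to_dataframe(rows: Sequence[FrequencyRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def write_frequency_table(rows: Sequence[FrequencyRow], path: str | Path) -> None:
    frequency_table_to_dataframe(rows).to_csv(path, index=False)
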