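"""Synthetic electronic-health-record generator with planted ground truth.

Real provincial registry data of this kind are not redistributable, so the
generator emulates the statistical structure the downstream analysis
assumes and makes every stage testable against known truth:

* a mixed cohort of Crohn's-like (CD), colitis-like (UC), unclassified
  (IBDU) and non-case patients;
* per-patient encounter streams that do or do not satisfy the two-year
  administrative case definition (>=2 hospitalizations OR >=4 physician
  claims OR >=2 ambulatory contacts carrying an IBD code inside a 730-day
  window);
* extraintestinal/autoimmune diagnosis codes drawn from a planted block
  (community) structure over codes, the classic planted-partition regime;
* first-diagnosis dates with a configurable temporal-ordering bias for
  designated (earlier, later) code pairs;
* demographics (sex, birth date) for age/sex stratification.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from ``config.seed``, so a fixed configuration reproduces byte-identical
output.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .records import EncounterRecord, read_records, write_records

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "read_ground_truth",
    "write_ground_truth",
    "read_records",
    "write_records",
]

_LABELS = ("CD", "UC", "IBDU", "non-case")

#: Chapter letters cycled when synthesizing the planted code pool, paired
#: with a base two-digit block that lands inside a mapped organ-system
#: domain (e.g. D needs >=50 to fall in the blood/immune block D50-D89,
#: H <60 to fall in the eye chapter). K is deliberately absent: K50/K51
#: are reserved for the IBD index codes.
_CHAPTER_BASES: Sequence[tuple[str, int]] = (
    ("F", 20), ("M", 20), ("N", 20), ("I", 60), ("J", 20), ("G", 20),
    ("E", 20), ("H", 20), ("D", 50), ("L", 20), ("R", 20),
)

_CD_CODES = ("K50.0", "K50.1", "K50.8", "K50.9")
_UC_CODES = ("K51.0", "K51.2", "K51.3", "K51.5", "K51.8", "K51.9")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_patients
        Cohort size including non-cases.
    disease_mix
        Proportions over CD / UC / IBDU / non-case, summing to 1. The
        default keeps the CD:UC:IBDU ratio of a large administrative IBD
        registry (roughly 0.52 : 0.39 : 0.09 among cases) with a 10%
        non-case fraction to exercise the classifier's reject path.
    n_communities, codes_per_community
        The planted block structure over extraintestinal/autoimmune codes.
    p_within, p_between
        Probability a patient carries each code of their assigned block /
        each out-of-block code. Defaults (0.3 / 0.01) give a strongly
        recoverable planted partition at the default cohort size.
    case_noise
        Fraction of IBD-labelled patients given sub-threshold encounter
        streams that violate all three case-definition clauses.
    temporal_bias
        Probability, for each designated ordered code pair a patient
        carries, that the "cause" code's first date strictly precedes the
        "effect" code's. 0.5 = no ordering signal, 1.0 = deterministic.
    date_span
        Closed calendar interval encounters are drawn from.
    """

    n_patients: int = 2000
    disease_mix: Mapping[str, float] = field(
        default_factory=lambda: {"CD": 0.47, "UC": 0.35, "IBDU": 0.08, "non-case": 0.10}
    )
    n_communities: int = 4
    codes_per_community: int = 25
    p_within: float = 0.3
    p_between: float = 0.01
    case_noise: float = 0.0
    temporal_bias: float = 0.8
    date_span: tuple[dt.date, dt.date] = (dt.date(2002, 1, 1), dt.date(2020, 12, 31))
    seed: int = 0
    repeat_encounter_prob: float = 0.2
    window_days: int = 730

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        missing = set(_LABELS) - set(self.disease_mix)
        if missing:
            raise ValueError(f"disease_mix missing labels: {sorted(missing)}")
        total = sum(self.disease_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"disease_mix must sum to 1, got {total}")
        for name in ("p_within", "p_between", "case_noise", "repeat_encounter_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.temporal_bias <= 1.0:
            raise ValueError("temporal_bias must be in [0.5, 1]")
        if self.n_communities < 1 or self.codes_per_community < 1:
            raise ValueError("n_communities and codes_per_community must be >= 1")
        if self.n_communities * self.codes_per_community < 2:
            raise ValueError("need at least 2 planted codes")
        if self.n_communities * self.codes_per_community > len(_CHAPTER_BASES) * 40:
            raise ValueError("planted code pool too large for the chapter layout")
        start, end = self.date_span
        if (end - start).days < self.window_days + 1:
            raise ValueError("date_span must exceed the case-definition window")


@dataclass
class GroundTruth:
    """Planted truth attached to a generated cohort."""

    patient_labels: dict[str, str]
    code_communities: dict[str, int]
    ordered_pairs: list[tuple[str, str]]
    patient_sex: dict[str, str] = field(default_factory=dict)
    patient_birth_date: dict[str, dt.date] = field(default_factory=dict)
    #: community each patient draws their within-block codes from
    patient_communities: dict[str, int] = field(default_factory=dict)


def _planted_codes(config: SimulationConfig) -> list[str]:
    """Deterministic code pool: chapters cycled, blocks contiguous."""
    n = config.n_communities * config.codes_per_community
    codes = []
    for i in range(n):
        letter, base = _CHAPTER_BASES[i % len(_CHAPTER_BASES)]
        offset = i // len(_CHAPTER_BASES)
        codes.append(f"{letter}{base + offset // 4:02d}.{offset % 4}")
    assert len(set(codes)) == n
    return codes


def _random_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    return start + dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def _case_stream(
    rng: np.random.Generator, config: SimulationConfig, index_codes: Sequence[str],
    pid: str,
) -> list[EncounterRecord]:
    """IBD encounters guaranteed to satisfy exactly one clause of the definition."""
    start, end = config.date_span
    clause = int(rng.integers(0, 3))
    etype, count = [
        ("hospitalization", 2), ("physician_claim", 4), ("ambulatory", 2)
    ][clause]
    span_days = (end - start).days
    anchor = int(rng.integers(0, span_days - config.window_days + 1))
    offsets = rng.integers(0, config.window_days, size=count)  # span <= window
    if len(index_codes) == 1:
        codes = [index_codes[0]] * count
    else:
        # IBDU streams alternate K50/K51 evenly so no subtype holds a majority;
        # CD/UC streams draw only their own family.
        codes = [index_codes[i % len(index_codes)] for i in range(count)]
    return [
        EncounterRecord(pid, start + dt.timedelta(days=anchor + int(o)), c, etype)
        for o, c in zip(offsets, codes)
    ]


def _noise_stream(
    rng: np.random.Generator, config: SimulationConfig, index_codes: Sequence[str],
    pid: str,
) -> list[EncounterRecord]:
    """Sub-threshold IBD encounters: 1 hospitalization + at most 2 claims."""
    start, end = config.date_span
    recs = [EncounterRecord(pid, _random_date(rng, start, end), index_codes[0], "hospitalization")]
    for _ in range(int(rng.integers(0, 3))):
        recs.append(
            EncounterRecord(
                pid, _random_date(rng, start, end), index_codes[-1], "physician_claim"
            )
        )
    return recs


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[EncounterRecord], GroundTruth]:
    """Generate an encounter stream and its planted ground truth.

    Deterministic for a fixed ``config`` (including the seed). IBD-labelled
    patients not selected as case-noise receive streams satisfying the case
    definition by construction; case-noise patients violate all three
    clauses; non-case patients carry at most one sub-threshold IBD claim.
    """
    rng = np.random.default_rng(config.seed)
    codes = _planted_codes(config)
    cpc = config.codes_per_community
    code_comm = {c: i // cpc for i, c in enumerate(codes)}
    ordered_pairs = [
        (codes[k * cpc + 2 * j], codes[k * cpc + 2 * j + 1])
        for k in range(config.n_communities)
        for j in range(cpc // 2)
    ]
    labels = list(_LABELS)
    mix = np.array([config.disease_mix[l] for l in labels])
    start, end = config.date_span

    truth = GroundTruth({}, dict(code_comm), list(ordered_pairs))
    records: list[EncounterRecord] = []
    width = max(4, len(str(max(config.n_patients - 1, 0))))

    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        label = labels[int(rng.choice(len(labels), p=mix))]
        truth.patient_labels[pid] = label
        truth.patient_sex[pid] = "female" if rng.random() < 0.5 else "male"
        # born strictly before the observation span so age is never negative
        birth_days = max((start - dt.date(1935, 1, 1)).days, 1)
        birth = dt.date(1935, 1, 1) + dt.timedelta(days=int(rng.integers(0, birth_days)))
        truth.patient_birth_date[pid] = birth

        # --- IBD index encounters ---------------------------------------
        if label == "CD":
            index_codes: Sequence[str] = (str(rng.choice(_CD_CODES)),)
        elif label == "UC":
            index_codes = (str(rng.choice(_UC_CODES)),)
        elif label == "IBDU":
            index_codes = ("K50.9", "K51.9")
        else:
            index_codes = ()

        if label == "non-case":
            if rng.random() < 0.5:
                records.append(
                    EncounterRecord(
                        pid, _random_date(rng, start, end), "K50.9", "physician_claim"
                    )
                )
        elif rng.random() < config.case_noise:
            records.extend(_noise_stream(rng, config, index_codes, pid))
        else:
            records.extend(_case_stream(rng, config, index_codes, pid))

        # --- planted extraintestinal codes ------------------------------
        own = int(rng.integers(0, config.n_communities))
        truth.patient_communities[pid] = own
        carried: dict[str, dt.date] = {}
        for code in codes:
            p = config.p_within if code_comm[code] == own else config.p_between
            if rng.random() < p:
                carried[code] = _random_date(rng, start, end)

        for cause, effect in ordered_pairs:
            if cause in carried and effect in carried:
                lo, hi = sorted((carried[cause], carried[effect]))
                if lo == hi:  # bias is defined on strict order
                    if hi < end:
                        hi = hi + dt.timedelta(days=1)
                    else:
                        lo = lo - dt.timedelta(days=1)
                if rng.random() < config.temporal_bias:
                    carried[cause], carried[effect] = lo, hi
                else:
                    carried[cause], carried[effect] = hi, lo

        for code in codes:  # fixed order for determinism
            if code not in carried:
                continue
            first = carried[code]
            etype = "physician_claim" if rng.random() < 0.8 else "ambulatory"
            records.append(EncounterRecord(pid, first, code, etype))
            if rng.random() < config.repeat_encounter_prob and first < end:
                later = _random_date(rng, first + dt.timedelta(days=1), end)
                records.append(EncounterRecord(pid, later, code, etype))

    return records, truth


# ---------------------------------------------------------------------------
# ground-truth serialization


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "patient_labels": truth.patient_labels,
        "code_communities": truth.code_communities,
        "ordered_pairs": [list(p) for p in truth.ordered_pairs],
        "patient_sex": truth.patient_sex,
        "patient_birth_date": {
            pid: d.isoformat() for pid, d in truth.patient_birth_date.items()
        },
        "patient_communities": truth.patient_communities,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        patient_labels=data["patient_labels"],
        code_communities={c: int(k) for c, k in data["code_communities"].items()},
        ordered_pairs=[tuple(p) for p in data["ordered_pairs"]],
        patient_sex=data.get("patient_sex", {}),
        patient_birth_date={
            pid: dt.date.fromisoformat(d)
            for pid, d in data.get("patient_birth_date", {}).items()
        },
        patient_communities={
            pid: int(k) for pid, k in data.get("patient_communities", {}).items()
        },
    )
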