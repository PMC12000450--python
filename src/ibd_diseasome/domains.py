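"""ICD-10 chapter grouping of diagnosis codes into organ-system domains.

A :class:`DomainMap` is an *ordered* list of (domain name, code ranges):
the first matching range wins, which lets narrow custom domains (here
"Cerebrovascular diseases", covering I60-I69 plus the venous
thromboembolism block I80-I82) take precedence over the general chapter
they would otherwise fall into. The IBD index codes K50/K51 map to a
reserved domain and are never counted as extraintestinal manifestations.

The default map is a reconstruction of the WHO ICD-10 chapter layout used
for organ-system tables; exact per-domain code membership in published
tables is rarely enumerated, so the map is a plain data structure that can
be serialized, edited and reloaded (JSON or YAML).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "IBD_INDEX_DOMAIN",
    "UNMAPPED",
    "CodeRange",
    "DomainMap",
    "default_domain_map",
]

#: Reserved domain name for the IBD index codes themselves (K50/K51).
IBD_INDEX_DOMAIN = "IBD index codes"

#: Fall-through pseudo-domain for codes no range covers.
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class CodeRange:
    """Inclusive range of ICD codes sharing one chapter letter, e.g. F00-F99."""

    letter: str
    lo: int
    hi: int

    def contains(self, code: str) -> bool:
        if not code or code[0] != self.letter:
            return False
        try:
            num = int(code[1:3])
        except (ValueError, IndexError):
            return False
        return self.lo <= num <= self.hi

    @classmethod
    def parse(cls, spec: str) -> "CodeRange":
        """Parse ``"F00-F99"`` or a single block ``"K50"``."""
        parts = spec.split("-")
        lo_letter, lo = parts[0][0], int(parts[0][1:3])
        if len(parts) == 1:
            return cls(lo_letter, lo, lo)
        hi_letter, hi = parts[1][0], int(parts[1][1:3])
        if hi_letter != lo_letter:
            raise ValueError(f"range {spec!r} spans chapter letters")
        return cls(lo_letter, lo, hi)

    def __str__(self) -> str:
        return f"{self.letter}{self.lo:02d}-{self.letter}{self.hi:02d}"


@dataclass
class DomainMap:
    """Ordered (domain name, code ranges) map; first matching range wins."""

    entries: list[tuple[str, list[CodeRange]]] = field(default_factory=list)

    def map_code(self, code: str) -> str:
        """Return the domain of *code*, or :data:`UNMAPPED`."""
        for name, ranges in self.entries:
            if any(r.contains(code) for r in ranges):
                return name
        return UNMAPPED

    def domain_names(self, include_ibd_index: bool = False) -> list[str]:
        names = [name for name, _ in self.entries]
        if not include_ibd_index:
            names = [n for n in names if n != IBD_INDEX_DOMAIN]
        return names

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "domains": [
                {"name": name, "ranges": [str(r) for r in ranges]}
                for name, ranges in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DomainMap":
        return cls(
            entries=[
                (d["name"], [CodeRange.parse(r) for r in d["ranges"]])
                for d in data["domains"]
            ]
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "DomainMap":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


_DEFAULT_ENTRIES: Sequence[tuple[str, Sequence[str]]] = (
    (IBD_INDEX_DOMAIN, ("K50-K51",)),
    ("Cerebrovascular diseases", ("I60-I69", "I80-I82")),
    ("Mental behavioral and neurodevelopmental disorders", ("F00-F99",)),
    ("Diseases of the musculoskeletal system and connective tissue", ("M00-M99",)),
    ("Diseases of the genitourinary system", ("N00-N99",)),
    ("Diseases of the circulatory system", ("I00-I99",)),
    ("Diseases of the respiratory system", ("J00-J99",)),
    (
        "Symptoms, signs and abnormal clinical and laboratory findings,"
        " not elsewhere classified",
        ("R00-R99",),
    ),
    ("Diseases of the digestive system", ("K00-K93",)),
    (
        "Diseases of the blood and blood-forming organs and certain disorders"
        " involving the immune mechanism",
        ("D50-D89",),
    ),
    ("Diseases of the skin and subcutaneous tissue", ("L00-L99",)),
    ("Diseases of the nervous system", ("G00-G99",)),
    ("Endocrine, nutritional and metabolic diseases", ("E00-E90",)),
    ("Diseases of the eye and adnexa", ("H00-H59",)),
    ("Diseases of the ear and mastoid process", ("H60-H95",)),
)


def default_domain_map() -> DomainMap:
    """Organ-system domain map over ICD-10 chapters.

    The IBD index range K50-K51 is listed first so Crohn's/colitis codes
    never count as extraintestinal; "Cerebrovascular diseases" precedes the
    circulatory chapter so I60-I69/I80-I82 land there.
    """
    return DomainMap(
        entries=[
            (name, [CodeRange.parse(r) for r in ranges])
            for name, ranges in _DEFAULT_ENTRIES
        ]
    )
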