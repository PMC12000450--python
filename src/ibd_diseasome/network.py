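"""Disease co-occurrence ("diseasome") graph construction.

Nodes are ICD codes sized by the number of unique patients carrying the
code (display size = sqrt(n) * 0.3 + 2.5); undirected edges connect code
pairs sharing at least one patient, weighted by the number m of unique
co-carrying patients (display width = m * 0.01). Each co-carrying patient
is classified by comparing the first-diagnosis dates of the two codes,
giving per-edge temporal direction counts (a-first, b-first, same-day).

Co-occurrence is lifetime (ever/ever): no time window is imposed between
the two first diagnoses. IBD index codes (K50.x/K51.x) are included as
nodes — they anchor the clusters — while codes outside the organ-system
domain map are dropped.

The graph retains its per-(patient, code) first-diagnosis-date table so
filters that merge codes (``max_code_length``) can recompute unique-patient
counts exactly instead of double-counting by summing child counts.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cohort import CohortLabel
from .domains import IBD_INDEX_DOMAIN, UNMAPPED, DomainMap, default_domain_map
from .freq import percent
from .records import EncounterRecord

__all__ = [
    "CodeEdge",
    "CodeNode",
    "CooccurrenceGraph",
    "build_graph",
    "edge_width",
    "filter_graph",
    "first_diagnosis_dates",
    "node_size",
    "read_graphml",
    "to_networkx",
    "write_edge_list",
    "write_graphml",
]

_TAG_LABELS = {"IBD": ("CD", "UC", "IBDU"), "CD": ("CD",), "UC": ("UC",)}


def node_size(n: int) -> float:
    """Display size of a node with *n* unique patients: sqrt(n)*0.3 + 2.5."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return math.sqrt(n) * 0.3 + 2.5


def edge_width(m: int) -> float:
    """Display thickness of an edge with *m* co-carrying patients: m*0.01."""
    if m < 0:
        raise ValueError("m must be >= 0")
    return m * 0.01


@dataclass(frozen=True)
class CodeNode:
    code: str
    label: str
    n_patients: int
    display_size: float
    domain: str
    n_per_disease: Mapping[str, int] = field(default_factory=dict)
    pct_per_disease: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CodeEdge:
    """Undirected edge; ``code_a < code_b`` lexicographically."""

    code_a: str
    code_b: str
    m_patients: int
    display_width: float
    dir_counts: tuple[int, int, int]  # (a_first, b_first, same_day)


@dataclass
class CooccurrenceGraph:
    nodes: dict[str, CodeNode]
    edges: dict[tuple[str, str], CodeEdge]
    cohort_tag: str = "IBD"
    #: (patient_id, code) -> first diagnosis date; kept for exact
    #: re-aggregation under code truncation. Not serialized.
    first_dates: dict[tuple[str, str], dt.date] = field(default_factory=dict)
    #: patient -> disease label, for per-disease node statistics.
    patient_labels: dict[str, str] = field(default_factory=dict)
    cohort_sizes: dict[str, int] = field(default_factory=dict)

    def same_topology(self, other: "CooccurrenceGraph") -> bool:
        """Equality of node and edge attribute sets (ignores raw tables)."""
        return (
            self.cohort_tag == other.cohort_tag
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


def first_diagnosis_dates(
    records: Iterable[EncounterRecord],
) -> dict[tuple[str, str], dt.date]:
    """Earliest encounter date per (patient, code)."""
    out: dict[tuple[str, str], dt.date] = {}
    for rec in records:
        key = (rec.patient_id, rec.icd_code)
        if key not in out or rec.date < out[key]:
            out[key] = rec.date
    return out


def _assemble(
    first_dates: Mapping[tuple[str, str], dt.date],
    cohort_tag: str,
    patient_labels: Mapping[str, str],
    cohort_sizes: Mapping[str, int],
    domain_map: DomainMap,
    descriptions: Mapping[str, str] | None,
    min_pair_count: int,
) -> CooccurrenceGraph:
    """Build node/edge tables from a first-diagnosis-date map."""
    by_patient: dict[str, list[tuple[str, dt.date]]] = {}
    patients_of_code: dict[str, set[str]] = {}
    for (pid, code), date in first_dates.items():
        by_patient.setdefault(pid, []).append((code, date))
        patients_of_code.setdefault(code, set()).add(pid)

    diseases = _TAG_LABELS[cohort_tag]
    nodes: dict[str, CodeNode] = {}
    for code in sorted(patients_of_code):
        pats = patients_of_code[code]
        n_per = {
            d: sum(1 for p in pats if patient_labels.get(p) == d) for d in diseases
        }
        pct_per = {
            d: percent(n_per[d], cohort_sizes[d])
            for d in diseases
            if cohort_sizes.get(d, 0) > 0
        }
        nodes[code] = CodeNode(
            code=code,
            label=(descriptions or {}).get(code, code),
            n_patients=len(pats),
            display_size=node_size(len(pats)),
            domain=domain_map.map_code(code),
            n_per_disease=n_per,
            pct_per_disease=pct_per,
        )

    acc: dict[tuple[str, str], list[int]] = {}
    for pid in sorted(by_patient):
        carried = sorted(by_patient[pid])
        for i in range(len(carried)):
            ca, da = carried[i]
            for j in range(i + 1, len(carried)):
                cb, db = carried[j]
                counts = acc.setdefault((ca, cb), [0, 0, 0])
                if da < db:
                    counts[0] += 1
                elif db < da:
                    counts[1] += 1
                else:
                    counts[2] += 1

    edges: dict[tuple[str, str], CodeEdge] = {}
    for (ca, cb), (a_first, b_first, same) in sorted(acc.items()):
        m = a_first + b_first + same
        if m < min_pair_count:
            continue
        edges[(ca, cb)] = CodeEdge(
            code_a=ca,
            code_b=cb,
            m_patients=m,
            display_width=edge_width(m),
            dir_counts=(a_first, b_first, same),
        )
    return CooccurrenceGraph(
        nodes=nodes,
        edges=edges,
        cohort_tag=cohort_tag,
        first_dates=dict(first_dates),
        patient_labels=dict(patient_labels),
        cohort_sizes=dict(cohort_sizes),
    )


def build_graph(
    records: Iterable[EncounterRecord],
    cohort: Iterable[CohortLabel],
    cohort_tag: str = "IBD",
    domain_map: DomainMap | None = None,
    descriptions: Mapping[str, str] | None = None,
    min_pair_count: int = 1,
    include_unmapped: bool = False,
) -> CooccurrenceGraph:
    """Build the co-occurrence graph for one disease network (IBD/CD/UC).

    Restricted to case patients whose subtype belongs to ``cohort_tag``;
    counts are over unique patients. IBD index codes are kept as nodes;
    unmapped codes are dropped unless ``include_unmapped``.
    """
    if cohort_tag not in _TAG_LABELS:
        raise ValueError(f"cohort_tag must be one of {sorted(_TAG_LABELS)}")
    dmap = domain_map or default_domain_map()
    diseases = _TAG_LABELS[cohort_tag]
    patient_labels = {
        c.patient_id: c.label for c in cohort if c.label in diseases
    }
    cohort_sizes = {
        d: sum(1 for l in patient_labels.values() if l == d) for d in diseases
    }

    kept = [
        rec
        for rec in records
        if rec.patient_id in patient_labels
        and (include_unmapped or dmap.map_code(rec.icd_code) != UNMAPPED)
    ]
    fd = first_diagnosis_dates(kept)
    return _assemble(
        fd, cohort_tag, patient_labels, cohort_sizes, dmap, descriptions,
        min_pair_count,
    )


def filter_graph(
    graph: CooccurrenceGraph,
    min_pair_count: int = 0,
    max_code_length: int | None = None,
    top_n_pairs: int | None = None,
    domain_subset: Sequence[str] | None = None,
    domain_map: DomainMap | None = None,
) -> CooccurrenceGraph:
    """Apply the interactive-app display filters, returning a new graph.

    ``max_code_length`` truncates codes to at most that many characters and
    re-aggregates n and m as unique-patient counts at the truncated level
    (recomputed from the stored first-diagnosis dates; merged first dates
    are the per-patient minimum over child codes). Edges with
    ``m < min_pair_count`` are dropped; only the ``top_n_pairs`` heaviest
    edges (ties broken lexicographically) are kept; nodes are restricted to
    ``domain_subset``; isolated nodes are removed after edge filtering.
    """
    if min_pair_count < 0 or (top_n_pairs is not None and top_n_pairs < 0):
        raise ValueError("thresholds must be >= 0")
    dmap = domain_map or default_domain_map()

    g = graph
    if max_code_length is not None:
        merged: dict[tuple[str, str], dt.date] = {}
        for (pid, code), date in g.first_dates.items():
            key = (pid, code[:max_code_length])
            if key not in merged or date < merged[key]:
                merged[key] = date
        g = _assemble(
            merged, g.cohort_tag, g.patient_labels, g.cohort_sizes, dmap, None, 1
        )

    nodes = dict(g.nodes)
    edges = dict(g.edges)
    if domain_subset is not None:
        allowed = set(domain_subset)
        nodes = {c: n for c, n in nodes.items() if n.domain in allowed}
        edges = {
            k: e for k, e in edges.items() if e.code_a in nodes and e.code_b in nodes
        }
    if min_pair_count:
        edges = {k: e for k, e in edges.items() if e.m_patients >= min_pair_count}
    if top_n_pairs is not None:
        ranked = sorted(edges.values(), key=lambda e: (-e.m_patients, e.code_a, e.code_b))
        edges = {(e.code_a, e.code_b): e for e in ranked[:top_n_pairs]}

    connected = {c for k in edges for c in k}
    nodes = {c: n for c, n in nodes.items() if c in connected}
    return replace(g, nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# export / import


def to_networkx(
    graph: CooccurrenceGraph, partition: Mapping[str, int] | None = None
) -> nx.Graph:
    """Convert to a :class:`networkx.Graph` with display attributes."""
    g = nx.Graph(cohort_tag=graph.cohort_tag)
    for code, node in graph.nodes.items():
        attrs = {
            "label": node.label,
            "n": node.n_patients,
            "size": node.display_size,
            "domain": node.domain,
        }
        for d, n in node.n_per_disease.items():
            attrs[f"n_{d}"] = int(n)
        for d, p in node.pct_per_disease.items():
            attrs[f"pct_{d}"] = float(p)
        if partition is not None:
            attrs["community"] = int(partition[code])
        g.add_node(code, **attrs)
    for edge in graph.edges.values():
        g.add_edge(
            edge.code_a,
            edge.code_b,
            m=edge.m_patients,
            width=edge.display_width,
            a_first=edge.dir_counts[0],
            b_first=edge.dir_counts[1],
            same_day=edge.dir_counts[2],
            weight=edge.m_patients,
        )
    return g


def write_graphml(
    graph: CooccurrenceGraph,
    path: str | Path,
    partition: Mapping[str, int] | None = None,
) -> None:
    nx.write_graphml(to_networkx(graph, partition), str(path))


def read_graphml(path: str | Path) -> CooccurrenceGraph:
    """Re-import a GraphML export (raw patient-level tables are not stored)."""
    g = nx.read_graphml(str(path))
    nodes = {}
    for code, a in g.nodes(data=True):
        nodes[code] = CodeNode(
            code=code,
            label=a.get("label", code),
            n_patients=int(a["n"]),
            display_size=float(a["size"]),
            domain=a.get("domain", UNMAPPED),
            n_per_disease={
                k[2:]: int(v) for k, v in a.items() if k.startswith("n_")
            },
            pct_per_disease={
                k[4:]: float(v) for k, v in a.items() if k.startswith("pct_")
            },
        )
    edges = {}
    for u, v, a in g.edges(data=True):
        ca, cb = sorted((u, v))
        edges[(ca, cb)] = CodeEdge(
            code_a=ca,
            code_b=cb,
            m_patients=int(a["m"]),
            display_width=float(a["width"]),
            dir_counts=(int(a["a_first"]), int(a["b_first"]), int(a["same_day"])),
        )
    return CooccurrenceGraph(
        nodes=nodes, edges=edges, cohort_tag=g.graph.get("cohort_tag", "IBD")
    )


def write_edge_list(graph: CooccurrenceGraph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code_a", "code_b", "m", "width", "a_first", "b_first", "same_day"])
        for e in sorted(graph.edges.values(), key=lambda e: (e.code_a, e.code_b)):
            writer.writerow(
                [e.code_a, e.code_b, e.m_patients, e.display_width, *e.dir_counts]
            )
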