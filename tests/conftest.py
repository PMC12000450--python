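"""Shared fixtures: tiny hand-built graphs and the planted-block cohort."""

from __future__ import annotations

import datetime as dt

import pytest

from ibd_diseasome.cohort import CaseDefinition, build_cohort
from ibd_diseasome.network import CodeEdge, CodeNode, CooccurrenceGraph, node_size
from ibd_diseasome.records import EncounterRecord
from ibd_diseasome.synthetic_ehr import SimulationConfig, generate_cohort


def make_graph(edges: dict[tuple[str, str], int], cohort_tag: str = "IBD") -> CooccurrenceGraph:
    """Build a CooccurrenceGraph directly from {(a, b): m} edge weights."""
    nodes: dict[str, CodeNode] = {}
    counts: dict[str, int] = {}
    for (a, b), m in edges.items():
        counts[a] = max(counts.get(a, 0), m)
        counts[b] = max(counts.get(b, 0), m)
    for code, n in counts.items():
        nodes[code] = CodeNode(
            code=code, label=code, n_patients=n, display_size=node_size(n),
            domain="test",
        )
    edge_objs = {}
    for (a, b), m in edges.items():
        ca, cb = sorted((a, b))
        edge_objs[(ca, cb)] = CodeEdge(
            code_a=ca, code_b=cb, m_patients=m, display_width=m * 0.01,
            dir_counts=(m, 0, 0),
        )
    return CooccurrenceGraph(nodes=nodes, edges=edge_objs, cohort_tag=cohort_tag)


def records_from_diagnoses(
    diagnoses: dict[str, dict[str, str]],
    encounter_type: str = "physician_claim",
) -> list[EncounterRecord]:
    """Records from {patient: {code: iso-date}} first-diagnosis maps."""
    return [
        EncounterRecord(pid, dt.date.fromisoformat(day), code, encounter_type)
        for pid, codes in diagnoses.items()
        for code, day in codes.items()
    ]


TWO_TRIANGLES = {
    ("A00", "B00"): 1, ("B00", "C00"): 1, ("A00", "C00"): 1,
    ("D00", "E00"): 1, ("E00", "F00"): 1, ("D00", "F00"): 1,
}


@pytest.fixture(scope="session")
def two_triangles():
    """Two disconnected equal-weight triangles: optimum is the two triangles, Q=0.5."""
    return make_graph(TWO_TRIANGLES)


@pytest.fixture(scope="session")
def planted_cohort():
    """The planted 4-block benchmark cohort: 2000 patients, 25 codes/block,
    p_within=0.3, p_between=0.01, no case noise, fixed seed."""
    config = SimulationConfig(
        n_patients=2000,
        n_communities=4,
        codes_per_community=25,
        p_within=0.3,
        p_between=0.01,
        case_noise=0.0,
        seed=7,
    )
    records, truth = generate_cohort(config)
    cohort = build_cohort(
        records, CaseDefinition(), sex=truth.patient_sex,
        birth_date=truth.patient_birth_date,
    )
    return config, records, truth, cohort
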