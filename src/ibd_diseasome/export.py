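"""Interactive-app data payload (vis-network node-link dialect).

The payload mirrors what a browser renderer needs: nodes with id, label,
display value, color and an HTML-free tooltip (code, full name, absolute
number and percent of patients per disease); edges with width and a
tooltip annotating the co-carrying patient count by temporal direction
(``A —> B`` first-diagnosis of A precedes B, ``<—`` the converse, ``==``
same day). Node positions are deliberately absent — layout belongs to the
renderer's physics engine.

Payloads are validated with pydantic models; ``vis_payload_schema()``
emits the corresponding JSON schema for consumers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from pydantic import BaseModel, Field

from .domains import DomainMap, default_domain_map
from .louvain import PALETTE, Partition, color_communities
from .network import CooccurrenceGraph

__all__ = [
    "ICD_DESCRIPTIONS",
    "VisEdge",
    "VisNode",
    "VisPayload",
    "describe_code",
    "export_vis_json",
    "vis_payload_schema",
]

#: Human-readable names for the IBD index codes; other codes fall back to
#: their organ-system domain. Users can pass a fuller description table.
ICD_DESCRIPTIONS: dict[str, str] = {
    "K50.0": "Crohn's disease of small intestine",
    "K50.1": "Crohn's disease of large intestine",
    "K50.8": "Crohn's disease of both small and large intestine",
    "K50.9": "Crohn's disease, unspecified",
    "K51.0": "Ulcerative (chronic) pancolitis",
    "K51.2": "Ulcerative (chronic) proctitis",
    "K51.3": "Ulcerative (chronic) rectosigmoiditis",
    "K51.4": "Inflammatory polyps of colon",
    "K51.5": "Left sided colitis",
    "K51.8": "Other ulcerative colitis",
    "K51.9": "Ulcerative colitis, unspecified",
}


def describe_code(
    code: str,
    descriptions: Mapping[str, str] | None = None,
    domain_map: DomainMap | None = None,
) -> str:
    table = {**ICD_DESCRIPTIONS, **(descriptions or {})}
    if code in table:
        return table[code]
    domain = (domain_map or default_domain_map()).map_code(code)
    return f"{domain} code {code}"


class VisNode(BaseModel):
    id: str
    label: str
    value: float = Field(ge=0)
    color: str
    title: str


class VisEdge(BaseModel):
    from_: str = Field(alias="from")
    to: str
    width: float = Field(ge=0)
    title: str

    model_config = {"populate_by_name": True}


class VisPayload(BaseModel):
    nodes: list[VisNode]
    edges: list[VisEdge]

    def validate_consistency(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids in payload")
        known = set(ids)
        for e in self.edges:
            if e.from_ not in known or e.to not in known:
                raise ValueError(f"edge {e.from_}--{e.to} references unknown node")


def _node_tooltip(node, descriptions, domain_map) -> str:
    lines = [f"{node.code} — {describe_code(node.code, descriptions, domain_map)}"]
    for disease, n in node.n_per_disease.items():
        pct = node.pct_per_disease.get(disease)
        pct_s = f" ({pct:.3f}%)" if pct is not None else ""
        lines.append(f"{disease}: {n} patients{pct_s}")
    return "\n".join(lines)


def _edge_tooltip(edge) -> str:
    a, b = edge.code_a, edge.code_b
    a_first, b_first, same = edge.dir_counts
    return (
        f"{a} / {b}: {edge.m_patients} patients | "
        f"{a} —> {b}: {a_first} | {a} <— {b}: {b_first} | {a} == {b}: {same}"
    )


def export_vis_json(
    graph: CooccurrenceGraph,
    partition: Partition | None = None,
    color_map: Mapping[int, str] | None = None,
    mode: str = "cluster",
    domain_map: DomainMap | None = None,
    descriptions: Mapping[str, str] | None = None,
    path: str | Path | None = None,
) -> VisPayload:
    """Build (and optionally write) the vis-network payload.

    ``mode="cluster"`` colors nodes by detected community (a partition is
    required and must cover the graph); ``mode="icd-hierarchy"`` colors by
    organ-system domain.
    """
    dmap = domain_map or default_domain_map()
    if mode not in ("cluster", "icd-hierarchy"):
        raise ValueError(f"mode must be 'cluster' or 'icd-hierarchy', got {mode!r}")

    if mode == "cluster":
        if partition is None:
            raise ValueError("cluster mode requires a partition")
        missing = sorted(set(graph.nodes) - set(partition.assignment))
        if missing:
            raise ValueError(f"partition misses graph nodes: {missing}")
        colors = dict(color_map or color_communities(partition))
        node_color = {c: colors[partition.assignment[c]] for c in graph.nodes}
    else:
        domains = sorted({n.domain for n in graph.nodes.values()})
        domain_color = {
            d: PALETTE[i % len(PALETTE)] for i, d in enumerate(domains)
        }
        node_color = {c: domain_color[n.domain] for c, n in graph.nodes.items()}

    payload = VisPayload(
        nodes=[
            VisNode(
                id=code,
                label=code,
                value=node.display_size,
                color=node_color[code],
                title=_node_tooltip(node, descriptions, dmap),
            )
            for code, node in sorted(graph.nodes.items())
        ],
        edges=[
            VisEdge.model_validate(
                {
                    "from": e.code_a,
                    "to": e.code_b,
                    "width": e.display_width,
                    "title": _edge_tooltip(e),
                }
            )
            for e in sorted(graph.edges.values(), key=lambda e: (e.code_a, e.code_b))
        ],
    )
    payload.validate_consistency()
    if path is not None:
        Path(path).write_text(payload.model_dump_json(by_alias=True, indent=2))
    return payload


def vis_payload_schema() -> dict:
    return VisPayload.model_json_schema(by_alias=True)


def load_vis_json(path: str | Path) -> VisPayload:
    payload = VisPayload.model_validate(json.loads(Path(path).read_text()))
    payload.validate_consistency()
    return payload
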