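"""Louvain modularity optimization, implemented from scratch.

The method greedily maximizes Newman-Girvan weighted modularity

    Q = (1/2W) * sum_ij [ w_ij - k_i * k_j / (2W) ] * delta(c_i, c_j)

where w_ij is the patient co-occurrence count of the code pair (i, j),
k_i the weighted degree and W the total edge weight, by alternating two
phases: (1) local moving — each node is greedily relocated to the
neighboring community with the largest positive modularity gain until no
move improves Q; (2) aggregation — communities collapse into super-nodes
(internal weight becomes a self-loop, counted twice in the degree) and
phase 1 repeats on the condensed graph.

Louvain's output depends on the order nodes are visited. Here that order
is derived *entirely* from the order of the input edge sequence (a node is
visited in the order of its first appearance among the edges), so the edge
order is the single source of run-to-run variability — which is exactly
the knob the robustness experiments shuffle. Given a graph and an edge
order the result is fully deterministic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import CooccurrenceGraph

__all__ = [
    "Partition",
    "color_communities",
    "louvain",
    "modularity",
    "write_partition_csv",
    "write_partition_json",
]

#: Move-acceptance tolerance; avoids float ping-pong between equal-gain moves.
_TOL = 1e-12

#: Cluster palette in descending community-size order.
PALETTE = (
    "blue", "yellow", "green", "red", "purple",
    "orange", "brown", "pink", "gray", "cyan", "olive", "magenta",
)


@dataclass(frozen=True)
class Partition:
    """A community assignment over graph nodes.

    ``assignment`` maps each code to a dense 0-based community id, ids
    ordered by descending community size (ties broken by the smallest
    member code); ``edge_order`` records the edge input sequence that
    produced the result, for exact reproducibility.
    """

    assignment: Mapping[str, int]
    modularity_Q: float
    edge_order: tuple[tuple[str, str], ...] = ()

    @property
    def n_communities(self) -> int:
        return max(self.assignment.values()) + 1 if self.assignment else 0

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for code, cid in self.assignment.items():
            out[cid].add(code)
        return out


def _edge_weights(graph: CooccurrenceGraph) -> dict[tuple[str, str], float]:
    return {k: float(e.m_patients) for k, e in graph.edges.items()}


def modularity(graph: CooccurrenceGraph, assignment: Mapping[str, int]) -> float:
    """Weighted Newman-Girvan modularity of an assignment (resolution 1).

    Self-loops are permitted (they arise from code aggregation) and their
    weight counts twice in the node degree, the standard adjacency-matrix
    convention.
    """
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses nodes: {sorted(missing)[:5]}")
    if not graph.edges:
        raise ValueError("modularity undefined on an edgeless graph")
    return _modularity_edges(_edge_weights(graph), graph.nodes.keys(), assignment)


def _modularity_edges(
    weights: Mapping[tuple[str, str], float],
    nodes,
    assignment: Mapping[str, int],
) -> float:
    k: dict[str, float] = {u: 0.0 for u in nodes}
    internal: dict[int, float] = {}
    for (u, v), w in weights.items():
        if u == v:
            k[u] += 2 * w
            internal[assignment[u]] = internal.get(assignment[u], 0.0) + 2 * w
        else:
            k[u] += w
            k[v] += w
            if assignment[u] == assignment[v]:
                internal[assignment[u]] = internal.get(assignment[u], 0.0) + 2 * w
    two_w = sum(k.values())
    tot: dict[int, float] = {}
    for u, deg in k.items():
        tot[assignment[u]] = tot.get(assignment[u], 0.0) + deg
    return sum(
        internal.get(c, 0.0) / two_w - (t / two_w) ** 2 for c, t in tot.items()
    )


def _local_move(
    n: int,
    adj: list[dict[int, float]],
    loops: list[float],
    order: Sequence[int],
) -> tuple[list[int], bool]:
    """Phase 1: greedy node relocation. Returns (community of node, moved?)."""
    k = [sum(adj[i].values()) + 2 * loops[i] for i in range(n)]
    two_w = sum(k)
    comm = list(range(n))
    tot = k[:]
    any_move = False
    improved = True
    while improved:
        improved = False
        for i in order:
            ci = comm[i]
            neigh_w: dict[int, float] = {}
            for j, w in adj[i].items():
                neigh_w[comm[j]] = neigh_w.get(comm[j], 0.0) + w
            tot[ci] -= k[i]
            # gain (up to the constant 1/2W) of joining community c
            stay = neigh_w.get(ci, 0.0) - tot[ci] * k[i] / two_w
            best_c, best_gain = ci, stay
            for c in sorted(neigh_w):
                if c == ci:
                    continue
                gain = neigh_w[c] - tot[c] * k[i] / two_w
                if gain > best_gain + _TOL:
                    best_c, best_gain = c, gain
            comm[i] = best_c
            tot[best_c] += k[i]
            if best_c != ci:
                improved = True
                any_move = True
    return comm, any_move


def _aggregate(
    n: int,
    adj: list[dict[int, float]],
    loops: list[float],
    comm: list[int],
    order: Sequence[int],
) -> tuple[int, list[dict[int, float]], list[float], list[int], dict[int, int]]:
    """Phase 2: collapse communities into super-nodes.

    Super-nodes are numbered by first appearance in the visit order, and the
    next level's visit order follows that same numbering, keeping the whole
    run a pure function of the original edge sequence.
    """
    renum: dict[int, int] = {}
    for i in order:
        if comm[i] not in renum:
            renum[comm[i]] = len(renum)
    n2 = len(renum)
    adj2: list[dict[int, float]] = [dict() for _ in range(n2)]
    loops2 = [0.0] * n2
    for i in range(n):
        ci = renum[comm[i]]
        loops2[ci] += loops[i]
        for j, w in adj[i].items():
            if j <= i:
                continue
            cj = renum[comm[j]]
            if ci == cj:
                loops2[ci] += w
            else:
                adj2[ci][cj] = adj2[ci].get(cj, 0.0) + w
                adj2[cj][ci] = adj2[cj].get(ci, 0.0) + w
    return n2, adj2, loops2, list(range(n2)), renum


def louvain(
    graph: CooccurrenceGraph,
    edge_order: Sequence[tuple[str, str]] | int | None = None,
) -> Partition:
    """Louvain community detection over a co-occurrence graph.

    Parameters
    ----------
    edge_order
        Explicit sequence of edge keys, an integer seed (edges are shuffled
        with that seed), or None for fixed alphabetical order. The node
        visit order — Louvain's only source of run-to-run variability — is
        derived from this sequence.

    Returns
    -------
    Partition
        Dense community ids sorted by descending community size (ties by
        smallest member code), with the exact modularity of the final
        assignment.
    """
    if not graph.edges:
        raise ValueError("louvain requires a graph with at least one edge")

    if edge_order is None:
        seq = sorted(graph.edges)
    elif isinstance(edge_order, (int, np.integer)):
        seq = sorted(graph.edges)
        rng = np.random.default_rng(int(edge_order))
        seq = [seq[i] for i in rng.permutation(len(seq))]
    else:
        seq = [tuple(e) for e in edge_order]
        if set(seq) != set(graph.edges) or len(seq) != len(graph.edges):
            raise ValueError("edge_order must be a permutation of the graph's edges")

    codes = sorted(graph.nodes)
    index = {c: i for i, c in enumerate(codes)}
    n = len(codes)
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    loops = [0.0] * n
    for (u, v) in seq:
        w = float(graph.edges[(u, v)].m_patients)
        iu, iv = index[u], index[v]
        if iu == iv:
            loops[iu] += w
        else:
            adj[iu][iv] = adj[iu].get(iv, 0.0) + w
            adj[iv][iu] = adj[iv].get(iu, 0.0) + w

    # node visit order = first appearance in the edge sequence, then any
    # isolated nodes in code order (they never move: zero degree).
    order: list[int] = []
    seen = set()
    for (u, v) in seq:
        for c in (u, v):
            if index[c] not in seen:
                seen.add(index[c])
                order.append(index[c])
    for i in range(n):
        if i not in seen:
            order.append(i)

    # membership of each original node through the levels
    member: list[int] = list(range(n))
    level_n, level_adj, level_loops, level_order = n, adj, loops, order
    prev_q = None
    while True:
        comm, moved = _local_move(level_n, level_adj, level_loops, level_order)
        assignment = {codes[i]: comm[member[i]] for i in range(n)}
        q = _modularity_edges(
            _edge_weights(graph), graph.nodes.keys(), assignment
        )
        if prev_q is not None and q - prev_q < _TOL:
            break
        prev_q = q
        if not moved:
            break
        level_n, level_adj, level_loops, level_order, renum = _aggregate(
            level_n, level_adj, level_loops, comm, level_order
        )
        member = [renum[comm[m]] for m in member]

    # final dense ids: descending size, ties by smallest member code
    final = {codes[i]: comm[member[i]] for i in range(n)}
    groups: dict[int, list[str]] = {}
    for code, cid in final.items():
        groups.setdefault(cid, []).append(code)
    ranked = sorted(
        groups.values(), key=lambda members: (-len(members), min(members))
    )
    assignment = {
        code: new_id for new_id, members in enumerate(ranked) for code in members
    }
    q = _modularity_edges(_edge_weights(graph), graph.nodes.keys(), assignment)
    return Partition(assignment=assignment, modularity_Q=q, edge_order=tuple(seq))


def color_communities(partition: Partition) -> dict[int, str]:
    """Fixed palette by descending community size (blue, yellow, green,
    red, purple, then an overflow palette)."""
    colors = {}
    for cid in range(partition.n_communities):
        colors[cid] = (
            PALETTE[cid] if cid < len(PALETTE) else f"community-{cid}"
        )
    return colors


def write_partition_csv(partition: Partition, path: str | Path) -> None:
    colors = color_communities(partition)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "community", "color"])
        for code in sorted(partition.assignment):
            cid = partition.assignment[code]
            writer.writerow([code, cid, colors[cid]])


def write_partition_json(partition: Partition, path: str | Path) -> None:
    colors = color_communities(partition)
    Path(path).write_text(
        json.dumps(
            {
                "assignment": dict(sorted(partition.assignment.items())),
                "modularity": partition.modularity_Q,
                "colors": {str(k): v for k, v in colors.items()},
            },
            indent=2,
        )
    )
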