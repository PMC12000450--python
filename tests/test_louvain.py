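"""Louvain and modularity: hand-derived values, exhaustive-search oracles on
small graphs, independent cross-check, determinism and planted recovery."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from ibd_diseasome.louvain import color_communities, louvain, modularity
from ibd_diseasome.network import build_graph
from ibd_diseasome.robustness import partition_overlap

from conftest import make_graph


def set_partitions(items):
    """All partitions of a set (recursive; fine up to ~10 items)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield partial + [[first]]


def exhaustive_best_q(graph):
    """Maximum modularity over all partitions, scored by networkx
    (independent of the package's own modularity implementation)."""
    nxg = nx.Graph()
    for code in graph.nodes:
        nxg.add_node(code)
    for e in graph.edges.values():
        nxg.add_edge(e.code_a, e.code_b, weight=e.m_patients)
    best_q, best_p = -1.0, None
    for partition in set_partitions(sorted(graph.nodes)):
        q = nx.community.modularity(nxg, [set(c) for c in partition], weight="weight")
        if q > best_q:
            best_q, best_p = q, partition
    return best_q, best_p


class TestModularity:
    def test_single_community_is_zero(self, two_triangles):
        assignment = {c: 0 for c in two_triangles.nodes}
        assert modularity(two_triangles, assignment) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_split_is_half(self, two_triangles):
        assignment = {c: (0 if c in ("A00", "B00", "C00") else 1) for c in two_triangles.nodes}
        assert modularity(two_triangles, assignment) == pytest.approx(0.5)

    def test_single_edge_split_is_minus_half(self):
        g = make_graph({("A00", "B00"): 1})
        assert modularity(g, {"A00": 0, "B00": 1}) == pytest.approx(-0.5)

    def test_edgeless_graph_raises(self):
        g = make_graph({("A00", "B00"): 1})
        g.edges = {}
        with pytest.raises(ValueError):
            modularity(g, {"A00": 0, "B00": 0})

    def test_incomplete_assignment_raises(self, two_triangles):
        with pytest.raises(ValueError):
            modularity(two_triangles, {"A00": 0})

    def test_invariant_under_label_permutation(self, two_triangles):
        a1 = {c: (0 if c in ("A00", "B00", "C00") else 1) for c in two_triangles.nodes}
        a2 = {c: 1 - v for c, v in a1.items()}
        assert modularity(two_triangles, a1) == modularity(two_triangles, a2)

    def test_agrees_with_networkx_on_random_graphs(self):
        """Cross-check against the independent reference on 50 random
        weighted graphs and random assignments."""
        rng = np.random.default_rng(42)
        for trial in range(50):
            n = int(rng.integers(4, 12))
            codes = [f"C{i:02d}" for i in range(n)]
            edges = {}
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.4:
                    edges[(codes[i], codes[j])] = int(rng.integers(1, 10))
            if not edges:
                continue
            g = make_graph(edges)
            assignment = {c: int(rng.integers(0, 3)) for c in g.nodes}
            # dense ids not required by modularity(); normalize anyway
            nxg = nx.Graph()
            nxg.add_nodes_from(g.nodes)
            nxg.add_weighted_edges_from((a, b, w) for (a, b), w in edges.items())
            comms = {}
            for c, k in assignment.items():
                comms.setdefault(k, set()).add(c)
            expected = nx.community.modularity(nxg, list(comms.values()), weight="weight")
            assert modularity(g, assignment) == pytest.approx(expected, abs=1e-9)


class TestLouvain:
    def test_two_triangles_exact_optimum(self, two_triangles):
        part = louvain(two_triangles, edge_order=None)
        assert part.n_communities == 2
        assert part.modularity_Q == pytest.approx(0.5)
        comms = part.communities()
        assert {frozenset(c) for c in comms} == {
            frozenset({"A00", "B00", "C00"}),
            frozenset({"D00", "E00", "F00"}),
        }

    def test_complete_graph_single_community(self):
        codes = [f"C{i}0" for i in range(5)]
        edges = {(a, b): 1 for a, b in itertools.combinations(codes, 2)}
        part = louvain(make_graph(edges), edge_order=None)
        assert part.n_communities == 1

    def test_attains_exhaustive_optimum_on_disconnected_cliques(self):
        """On the disconnected-cliques family Louvain reaches the exact
        enumerated optimum."""
        for sizes in [(3, 3), (4, 3), (3, 3, 2)]:
            edges = {}
            offset = 0
            for s in sizes:
                codes = [f"C{offset + i:02d}" for i in range(s)]
                for a, b in itertools.combinations(codes, 2):
                    edges[(a, b)] = 1
                offset += s
            g = make_graph(edges)
            best_q, _ = exhaustive_best_q(g)
            part = louvain(g, edge_order=None)
            assert part.modularity_Q == pytest.approx(best_q, abs=1e-12)
            assert part.n_communities == len(sizes)

    def test_near_optimal_on_small_connected_graphs(self):
        """Louvain Q >= 0.95 x exhaustive optimum on random connected graphs
        with <= 8 nodes."""
        rng = np.random.default_rng(7)
        tested = 0
        while tested < 8:
            n = int(rng.integers(5, 9))
            codes = [f"C{i:02d}" for i in range(n)]
            edges = {}
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.45:
                    edges[(codes[i], codes[j])] = int(rng.integers(1, 5))
            if not edges:
                continue
            g = make_graph(edges)
            nxg = nx.Graph()
            nxg.add_nodes_from(g.nodes)
            nxg.add_weighted_edges_from((a, b, w) for (a, b), w in edges.items())
            if not nx.is_connected(nxg):
                continue
            tested += 1
            best_q, _ = exhaustive_best_q(g)
            part = louvain(g, edge_order=None)
            if best_q > 0:
                assert part.modularity_Q >= 0.95 * best_q
            else:
                assert part.modularity_Q >= best_q - 1e-12

    def test_deterministic_given_order(self, two_triangles):
        p1 = louvain(two_triangles, edge_order=123)
        p2 = louvain(two_triangles, edge_order=123)
        assert p1.assignment == p2.assignment
        assert p1.edge_order == p2.edge_order

    def test_q_matches_recomputation(self, planted_cohort):
        _, records, _, cohort = planted_cohort
        g = build_graph(records, cohort, "IBD")
        part = louvain(g, edge_order=None)
        assert part.modularity_Q == pytest.approx(
            modularity(g, part.assignment), abs=1e-12
        )

    def test_dense_ids_sorted_by_size(self, planted_cohort):
        _, records, _, cohort = planted_cohort
        g = build_graph(records, cohort, "IBD")
        part = louvain(g, edge_order=None)
        sizes = [len(c) for c in part.communities()]
        assert sorted(set(part.assignment.values())) == list(range(len(sizes)))
        assert sizes == sorted(sizes, reverse=True)

    def test_edgeless_graph_raises(self):
        g = make_graph({("A00", "B00"): 1})
        g.edges = {}
        with pytest.raises(ValueError):
            louvain(g)

    def test_bad_edge_order_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            louvain(two_triangles, edge_order=[("A00", "B00")])

    def test_planted_four_block_recovery(self, planted_cohort):
        """Matched Dice vs the planted blocks >= 0.9 on the benchmark cohort."""
        _, records, truth, cohort = planted_cohort
        g = build_graph(records, cohort, "IBD")
        part = louvain(g, edge_order=None)
        planted = {}
        for code, k in truth.code_communities.items():
            if code in g.nodes:
                planted.setdefault(k, set()).add(code)
        detected = [
            s & set(truth.code_communities) for s in part.communities()
        ]
        detected = [s for s in detected if s]
        score = partition_overlap(detected, list(planted.values()))
        assert score >= 0.9


class TestColors:
    def test_palette_order(self):
        # 5 communities sized 150>120>80>40>30 -> blue,yellow,green,red,purple
        edges = {}
        offset = 0
        for size in (6, 5, 4, 3, 2):
            codes = [f"C{offset + i:02d}" for i in range(size)]
            for a, b in itertools.combinations(codes, 2):
                edges[(a, b)] = 10
            offset += size
        part = louvain(make_graph(edges), edge_order=None)
        colors = color_communities(part)
        assert [colors[i] for i in range(5)] == ["blue", "yellow", "green", "red", "purple"]

    def test_single_community_blue(self):
        codes = ["A00", "B00", "C00"]
        edges = {(a, b): 1 for a, b in itertools.combinations(codes, 2)}
        part = louvain(make_graph(edges), edge_order=None)
        colors = color_communities(part)
        assert colors[0] == "blue"

    def test_size_ties_broken_lexicographically(self, two_triangles):
        part = louvain(two_triangles, edge_order=None)
        # equal sizes: community 0 must contain the lexicographically
        # smallest code (A00)
        assert part.assignment["A00"] == 0
        assert part.assignment["D00"] == 1
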