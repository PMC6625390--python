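import logging
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from ppinet.fixtures import random_network
from ppinet.genomic import GoAnnotationSet
from ppinet.network import (
    InteractionNetwork,
    edge_shuffle_null,
    go_term_enrichment,
    interaction_enrichment,
    overlap_fisher,
    pathway_interactors,
    topology_summary,
)
from ppinet.pairs import PathwayCoreSet


def exact_fisher_greater(x12, x1, x2, n):
    """Exact integer-arithmetic hypergeometric tail P(overlap >= x12)."""
    total = Fraction(0)
    denom = math.comb(n, x2)
    for j in range(x12, min(x1, x2) + 1):
        if x2 - j > n - x1:
            continue
        total += Fraction(math.comb(x1, j) * math.comb(n - x1, x2 - j), denom)
    return float(total)


class TestPathwayInteractors:
    def test_star_graph_hub_core(self):
        net = InteractionNetwork.from_pairs([("HUB", f"L{i}") for i in range(1, 6)])
        cores = PathwayCoreSet(name="GA", cores={"HUB"})
        assert pathway_interactors(net, cores) == {f"L{i}" for i in range(1, 6)}

    def test_isolated_core_yields_empty_set(self):
        graph = nx.Graph()
        graph.add_edge("A1", "B1")
        graph.add_node("LONER")
        net = InteractionNetwork(graph)
        assert pathway_interactors(net, PathwayCoreSet(name="x", cores={"LONER"})) == set()

    def test_matches_adjacency_scan(self):
        net = random_network(50, 120, seed=3)
        nodes = sorted(net.graph.nodes)
        cores = PathwayCoreSet(name="x", cores=set(nodes[:5]))
        result = pathway_interactors(net, cores)
        oracle = set()
        for core in cores.cores:
            for u, v in net.graph.edges():
                if u == core:
                    oracle.add(v)
                elif v == core:
                    oracle.add(u)
        assert result == oracle - cores.cores

    def test_cores_included_on_request(self):
        net = InteractionNetwork.from_pairs([("A1", "B1"), ("B1", "C1")])
        cores = PathwayCoreSet(name="x", cores={"A1", "B1"})
        assert "B1" in pathway_interactors(net, cores, include_cores=True)

    def test_absent_cores_error(self):
        net = InteractionNetwork.from_pairs([("A1", "B1")])
        with pytest.raises(ValueError):
            pathway_interactors(net, PathwayCoreSet(name="x", cores={"Z9"}))


class TestOverlapFisher:
    def test_maximal_overlap_highly_significant(self):
        s = {f"P{i}" for i in range(10)}
        test = overlap_fisher(s, s, 100)
        assert test.x12 == 10 and test.p_value < 1e-10

    def test_disjoint_small_sets_not_significant(self):
        a = {"A1", "A2"}
        b = {"B1", "B2"}
        assert overlap_fisher(a, b, 1000).p_value > 0.99

    def test_exhaustive_enumeration_oracle(self):
        # the [[5,5],[5,85]] layout: X12=5, X1=X2=10, N=100
        a = {f"C{i}" for i in range(5)} | {f"A{i}" for i in range(5)}
        b = {f"C{i}" for i in range(5)} | {f"B{i}" for i in range(5)}
        test = overlap_fisher(a, b, 100)
        assert test.table == [[5, 5], [5, 85]]
        assert test.p_value == pytest.approx(exact_fisher_greater(5, 10, 10, 100), abs=1e-12)

    def test_symmetry_and_cell_sum(self):
        rng = np.random.default_rng(8)
        pool = [f"G{i}" for i in range(40)]
        for _ in range(20):
            a = set(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            b = set(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            ab = overlap_fisher(a, b, 40)
            ba = overlap_fisher(b, a, 40)
            assert ab.p_value == pytest.approx(ba.p_value, abs=1e-14)
            assert sum(sum(row) for row in ab.table) == 40

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            overlap_fisher({f"P{i}" for i in range(30)}, {f"Q{i}" for i in range(30)}, 40)


class TestEdgeShuffle:
    def test_degree_sequence_preserved_every_replicate(self):
        net = random_network(30, 60, seed=1)
        original = dict(net.graph.degree())
        for replicate in edge_shuffle_null(net, r=50, seed=5):
            assert dict(replicate.degree()) == original
            assert nx.number_of_selfloops(replicate) == 0
            assert replicate.number_of_edges() == 60  # simple graph: no multi-edges

    def test_four_cycle_stays_within_valid_wirings(self):
        cycle = InteractionNetwork(nx.cycle_graph(4))
        # degree-2-everywhere graphs on 4 labelled nodes: the 3 perfect 4-cycles
        valid = set()
        for g in (
            [(0, 1), (1, 2), (2, 3), (3, 0)],
            [(0, 2), (2, 1), (1, 3), (3, 0)],
            [(0, 1), (1, 3), (3, 2), (2, 0)],
        ):
            valid.add(frozenset(frozenset(e) for e in g))
        for replicate in edge_shuffle_null(cycle, r=20, seed=2):
            assert frozenset(frozenset(e) for e in replicate.edges()) in valid

    def test_rigid_triangle_unchanged_with_warning(self, caplog):
        triangle = InteractionNetwork(nx.complete_graph(3))
        with caplog.at_level(logging.WARNING):
            replicates = list(edge_shuffle_null(triangle, r=2, seed=0))
        for replicate in replicates:
            assert set(map(frozenset, replicate.edges())) == set(
                map(frozenset, triangle.graph.edges())
            )
        assert any("swap" in r.message for r in caplog.records)

    def test_tiny_graph_rejected(self):
        with pytest.raises(ValueError):
            next(edge_shuffle_null(InteractionNetwork.from_pairs([("A1", "B1")]), r=1))


class TestInteractionEnrichment:
    def test_planted_enrichment_large_fold(self):
        rng = np.random.default_rng(4)
        graph = nx.gnm_random_graph(40, 60, seed=4)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        cores_a = {"N0", "N1", "N2"}
        cores_b = {"N3", "N4", "N5"}
        for a in cores_a:
            for b in cores_b:
                graph.add_edge(a, b)
        net = InteractionNetwork(graph)
        test = interaction_enrichment(net, cores_a, cores_b, r=100, seed=1)
        assert test.fold > 3
        assert test.p_value < 0.05

    def test_zero_observed_zero_fold(self):
        net = random_network(30, 50, seed=9)
        nodes = sorted(net.graph.nodes)
        isolated = nx.Graph(net.graph)
        a, b = {nodes[0]}, {nodes[1]}
        isolated.remove_edges_from(
            [(u, v) for u, v in isolated.edges() if {u, v} & (a | b)]
        )
        isolated.add_edges_from([(nodes[0], nodes[5]), (nodes[1], nodes[6])])
        test = interaction_enrichment(InteractionNetwork(isolated), a, b, r=50, seed=2)
        assert test.observed == 0 and test.fold == 0.0

    def test_non_enriched_random_graph_concentrates_near_one(self):
        net = random_network(30, 90, seed=11)
        nodes = sorted(net.graph.nodes)
        test = interaction_enrichment(net, set(nodes[:6]), set(nodes[6:12]), r=200, seed=3)
        if test.observed > 0:
            assert 0.4 < test.fold < 2.5
        assert test.p_value > 0.001


class TestGoEnrichment:
    def make_annotations(self):
        parents = {"root": set(), "special": {"root"}, "other": {"root"}}
        direct = {"BP": {}}
        for i in range(10):
            direct["BP"][f"S{i}"] = {"special"}
        for i in range(90):
            direct["BP"][f"O{i}"] = {"other"}
        return GoAnnotationSet(direct=direct, parents=parents)

    def test_planted_term_top_ranked(self):
        annot = self.make_annotations()
        table = go_term_enrichment({f"S{i}" for i in range(10)}, annot)
        assert table.index[0] == "special"
        assert table.loc["special", "fdr"] < 1e-6

    def test_random_set_not_enriched(self):
        annot = self.make_annotations()
        rng = np.random.default_rng(6)
        genes = [f"O{i}" for i in range(90)] + [f"S{i}" for i in range(10)]
        study = set(rng.choice(genes, size=10, replace=False))
        table = go_term_enrichment(study, annot)
        assert table["fdr"].min() > 0.05

    def test_term_without_study_members_p_one(self):
        annot = self.make_annotations()
        table = go_term_enrichment({f"O{i}" for i in range(5)}, annot)
        assert table.loc["special", "p"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            go_term_enrichment(set(), self.make_annotations())


class TestTopology:
    def test_complete_graph_clustering_one(self):
        summary = topology_summary(InteractionNetwork(nx.complete_graph(5)))
        assert summary.average_clustering == pytest.approx(1.0)

    def test_tree_clustering_zero(self):
        summary = topology_summary(
            InteractionNetwork(nx.balanced_tree(2, 3))
        )
        assert summary.average_clustering == 0.0

    def test_preferential_attachment_negative_slope(self):
        graph = nx.barabasi_albert_graph(400, 2, seed=12)
        summary = topology_summary(InteractionNetwork(graph))
        assert summary.powerlaw_slope < -0.5
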