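"""Case-study operators: pattern subnetworks, shared neighbors, candidates, ego nets."""

from __future__ import annotations

import numpy as np
import pytest

from hetmotif.graph import TypedGraph
from hetmotif.motifs import MotifPattern, census
from hetmotif.neighborhood import (
    ego_subnetwork,
    pattern_subnetwork,
    prioritize_candidates,
    shared_neighbors,
)
from conftest import random_typed_graph


TRI_DDG = MotifPattern.triangle("disease", "disease", "gene")


class TestPatternSubnetwork:
    def test_single_triangle(self, toy_triangle):
        sub = pattern_subnetwork(toy_triangle, TRI_DDG, [("d1", "d2", "g1")])
        assert sub.node_counts == {"disease": 2, "drug": 0, "gene": 1}
        assert sub.per_layer_edge_counts["disease-disease"] == 1
        assert sub.per_layer_edge_counts["disease-gene"] == 2

    def test_overlapping_matches_count_nodes_once(self, toy_triangle):
        g = toy_triangle
        g.add_edge("d3", "disease", "d1", "disease")
        g.add_edge("d3", "disease", "g1", "gene")
        sub = pattern_subnetwork(
            g, TRI_DDG, [("d1", "d2", "g1"), ("d1", "d3", "g1")]
        )
        assert sub.node_counts["disease"] == 3 and sub.node_counts["gene"] == 1

    def test_induced_edges_include_non_match_associations(self):
        # the two matches never use the d1-d2 association, but induction keeps it
        g = TypedGraph()
        g.add_edge("d1", "disease", "g1", "gene")
        g.add_edge("d2", "disease", "g1", "gene")
        g.add_edge("d1", "disease", "d2", "disease")
        g.add_edge("d1", "disease", "g2", "gene")
        g.add_edge("d2", "disease", "g2", "gene")
        pat = MotifPattern.path("gene", "disease", "disease")
        sub = pattern_subnetwork(g, pat, [("d1", "d2", "g1"), ("d1", "d2", "g2")])
        assert sub.per_layer_edge_counts["disease-disease"] == 1

    def test_empty_match_list_warns(self, toy_triangle):
        with pytest.warns(UserWarning):
            sub = pattern_subnetwork(toy_triangle, TRI_DDG, [])
        assert sub.graph.n_nodes == 0

    def test_against_brute_force_induction(self, rng):
        g = random_typed_graph(rng)
        c = census(g, keep_matches=True)
        pat = max(c.counts, key=lambda p: c.counts[p])
        sub = pattern_subnetwork(g, pat, c.matches[pat])
        nodes = {n for trip in c.matches[pat] for n in trip}
        expected_edges = {
            (a, b) for a, b in g.edges() if a in nodes and b in nodes
        }
        assert set(sub.graph.edges()) == expected_edges
        assert set(sub.graph.nodes) == nodes


class TestSharedNeighbors:
    def _two_anchor_graph(self):
        g = TypedGraph()
        for gene in ("g1", "g2", "g3"):
            g.add_edge("a", "disease", gene, "gene")
        for gene in ("g2", "g3", "g4"):
            g.add_edge("b", "disease", gene, "gene")
        g.add_edge("a", "disease", "x", "drug")  # off-type neighbor, ignored
        return g

    def test_partition(self):
        rep = shared_neighbors(self._two_anchor_graph(), "a", "b", "gene")
        assert rep.shared == {"g2", "g3"}
        assert rep.only_a == {"g1"} and rep.only_b == {"g4"}

    def test_identical_neighborhoods(self):
        g = TypedGraph()
        for gene in ("g1", "g2"):
            g.add_edge("a", "disease", gene, "gene")
            g.add_edge("b", "disease", gene, "gene")
        rep = shared_neighbors(g, "a", "b", "gene")
        assert rep.only_a == set() == rep.only_b and rep.shared == {"g1", "g2"}

    def test_missing_node_errors(self):
        with pytest.raises(KeyError, match="ghost"):
            shared_neighbors(self._two_anchor_graph(), "a", "ghost", "gene")

    def test_partition_property_on_random_graphs(self, rng):
        g = random_typed_graph(rng)
        diseases = g.nodes_of_type("disease")
        if len(diseases) < 2:
            pytest.skip("no disease pair in this draw")
        a, b = diseases[0], diseases[1]
        rep = shared_neighbors(g, a, b, "gene")
        assert rep.shared.isdisjoint(rep.only_a)
        assert rep.shared.isdisjoint(rep.only_b)
        assert rep.only_a.isdisjoint(rep.only_b)
        union = rep.shared | rep.only_a | rep.only_b
        oracle = {
            n
            for n in (g.neighbors(a) | g.neighbors(b))
            if g.node_type(n) == "gene"
        }
        assert union == oracle


class TestPrioritizeCandidates:
    def test_simple_case(self):
        g = TypedGraph()
        g.add_edge("src", "disease", "g1", "gene")
        g.add_edge("src", "disease", "g2", "gene")
        g.add_edge("tgt", "disease", "g2", "gene")
        assert prioritize_candidates(g, "src", "tgt", "gene") == ["g1"]

    def test_target_covering_all_genes_gives_empty(self):
        g = TypedGraph()
        for gene in ("g1", "g2"):
            g.add_edge("src", "disease", gene, "gene")
            g.add_edge("tgt", "disease", gene, "gene")
        assert prioritize_candidates(g, "src", "tgt", "gene") == []

    def test_unmet_premise_warns(self):
        g = TypedGraph()
        g.add_edge("src", "disease", "g1", "gene")
        g.add_edge("tgt", "disease", "g2", "gene")
        with pytest.warns(UserWarning):
            assert prioritize_candidates(g, "src", "tgt", "gene") == []

    def test_case_study_structure_35_shared_10_exclusive(self):
        # two diseases sharing 35 genes; 10 genes on the source side only ->
        # exactly those 10 come back as candidates
        g = TypedGraph()
        shared = [f"gs{i:02d}" for i in range(35)]
        only = [f"go{i:02d}" for i in range(10)]
        for x in shared:
            g.add_edge("tumor growth", "disease", x, "gene")
            g.add_edge("prostate neoplasm", "disease", x, "gene")
        for x in only:
            g.add_edge("tumor growth", "disease", x, "gene")
        out = prioritize_candidates(g, "tumor growth", "prostate neoplasm", "gene")
        assert sorted(out) == only

    def test_output_never_adjacent_to_target(self, rng):
        g = random_typed_graph(rng)
        diseases = g.nodes_of_type("disease")
        if len(diseases) < 2:
            pytest.skip("no disease pair in this draw")
        import warnings

        for a in diseases[:5]:
            for b in diseases[:5]:
                if a == b:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for c in prioritize_candidates(g, a, b, "gene"):
                        assert not g.has_edge(c, b)


class TestEgoSubnetwork:
    def test_star_center(self, disease_gene_star):
        sub = ego_subnetwork(disease_gene_star, "g1", radius=1)
        assert sub.n_nodes == 4 and sub.n_edges == 3

    def test_radius_one_around_leaf(self, disease_gene_star):
        sub = ego_subnetwork(disease_gene_star, "d1", radius=1)
        assert set(sub.nodes) == {"d1", "g1"} and sub.n_edges == 1

    def test_missing_center_errors(self, disease_gene_star):
        with pytest.raises(KeyError):
            ego_subnetwork(disease_gene_star, "nope")

    def test_bfs_oracle_and_radius_monotonicity(self, rng):
        import networkx as nx

        g = random_typed_graph(rng)
        center = sorted(g.nodes)[0]
        gx = g.to_networkx()
        for radius in (1, 2, 3):
            sub = ego_subnetwork(g, center, radius=radius)
            expected = {
                n
                for n, d in nx.single_source_shortest_path_length(
                    gx, center, cutoff=radius
                ).items()
            }
            assert set(sub.nodes) == expected
        smaller = ego_subnetwork(g, center, radius=1)
        larger = ego_subnetwork(g, center, radius=2)
        assert set(smaller.nodes) <= set(larger.nodes)
        assert set(smaller.edges()) <= set(larger.edges())
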