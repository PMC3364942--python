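"""Closure, CCC partitioning, gap recovery, filtering and Potential generation."""

import itertools
import random

import networkx as nx
import pytest

import metabolon as mb
from conftest import make_toy_data
from oracles import closure_oracle, gap_members_oracle


def edge_set(graph):
    return {frozenset(e) for e in graph.edges}


class TestClosure:
    def test_path_gains_the_three_gap_edge(self):
        graph = nx.path_graph(["v1", "v2", "v3", "v4", "v5"])
        closed = mb.partial_transitive_closure(graph, 3)
        assert closed.has_edge("v1", "v5")
        assert closed.edges["v1", "v5"]["closure"]
        assert not closed.edges["v1", "v2"]["closure"]

    def test_zero_gaps_changes_nothing(self):
        graph = nx.gnp_random_graph(12, 0.3, seed=7)
        closed = mb.partial_transitive_closure(graph, 0)
        assert edge_set(closed) == edge_set(graph)

    def test_six_cycle_with_two_gaps_becomes_complete(self):
        closed = mb.partial_transitive_closure(nx.cycle_graph(6), 2)
        # max distance on a 6-cycle is 3 = g+1: all 15 pairs joined
        assert closed.number_of_edges() == 15

    @pytest.mark.parametrize("g", [0, 1, 2, 4])
    def test_matches_all_pairs_bfs_oracle(self, g):
        rng = random.Random(g)
        graph = nx.gnp_random_graph(15, 0.18, seed=rng.randint(0, 999))
        closed = mb.partial_transitive_closure(graph, g)
        assert edge_set(closed) == closure_oracle(graph, g)


class TestPartition:
    def test_toy_forms_a_single_ccc(self, toy_data):
        metabolons = mb.find_metabolons(toy_data)
        assert len(metabolons) == 1
        m = metabolons[0]
        assert m.genes == ["gA", "gB", "gC", "gD", "gE", "gF"]
        assert m.gap_genes == ["gB", "gE"]
        assert m.reactions == ["r1", "r2", "r3", "r4", "r5"]
        assert m.gap_reactions == ["r4"]

    def test_gene_clusters_on_separate_replicons_split_the_ccc(self):
        data = make_toy_data(
            config=mb.Config(min_genes=1, min_rxns=1, min_known=1,
                             circular_replicons=False),
            replicon_of={"gD": "rep2", "gE": "rep2", "gF": "rep2"},
        )
        metabolons = mb.find_metabolons(data)
        assert len(metabolons) == 2

    def test_every_known_association_lands_in_exactly_one_ccc(self, toy_data):
        closures = mb.prepare_closures(toy_data)
        blocks = mb.partition_cccs(
            toy_data.known_by_organism("org1"), closures.gene["org1"],
            closures.reaction,
        )
        keys = [a.key for block in blocks for a in block]
        assert sorted(keys) == sorted(a.key for a in toy_data.associations)
        assert len(keys) == len(set(keys))

    def test_fixed_point_is_independent_of_input_order(self, toy_data):
        closures = mb.prepare_closures(toy_data)
        assocs = toy_data.known_by_organism("org1")
        reference = None
        for perm in itertools.permutations(assocs):
            blocks = mb.partition_cccs(
                list(perm), closures.gene["org1"], closures.reaction
            )
            shape = {frozenset(a.key for a in b) for b in blocks}
            reference = reference or shape
            assert shape == reference


class TestGapRecovery:
    def test_single_unannotated_gene_between_anchors_is_recovered(self):
        data = make_toy_data(known=[("gA", "r1"), ("gC", "r2")])
        m = mb.find_metabolons(data)[0]
        assert m.gap_genes == ["gB"]

    def test_anchors_beyond_the_gap_limit_fall_apart(self):
        # gA ... 4 unannotated genes ... gF: distance 5 > g_gene + 1 = 4
        data = make_toy_data(
            known=[("gA", "r1"), ("gF", "r2")],
            config=mb.Config(min_genes=1, min_rxns=1, min_known=1,
                             circular_replicons=False),
        )
        metabolons = mb.find_metabolons(data)
        assert len(metabolons) == 2
        assert all(m.gap_genes == [] for m in metabolons)

    def test_reaction_interior_recovered_at_distance_three(self):
        # Known reactions r1 and r4 at distance 3 <= g_rxn + 1: both interior
        # reactions come back as gaps
        data = make_toy_data(known=[("gA", "r1"), ("gB", "r4")])
        m = mb.find_metabolons(data)[0]
        assert m.gap_reactions == ["r2", "r3"]

    def test_interior_vertices_match_distance_sum_oracle(self, toy_data):
        m = mb.find_metabolons(toy_data)[0]
        anchors = {a.gene_id for a in m.known_associations}
        expected = gap_members_oracle(anchors, toy_data.gene_graphs["org1"], 3)
        assert set(m.genes) == expected
        anchors_r = {a.reaction_id for a in m.known_associations}
        expected_r = gap_members_oracle(anchors_r, toy_data.reaction_graph, 2)
        assert set(m.reactions) == expected_r


class TestFilter:
    def make_metabolon(self, n_genes, n_rxns, n_known):
        gene_ids = [f"g{i}" for i in range(n_genes)]
        rxn_ids = [f"r{i}" for i in range(n_rxns)]
        assocs = [
            mb.Association("org1", gene_ids[i % n_genes], rxn_ids[i % n_rxns])
            for i in range(n_known)
        ]
        return mb.Metabolon(
            "M1", "org1",
            {g: False for g in gene_ids}, {r: False for r in rxn_ids},
            [], [], assocs,
        )

    def test_thresholds_are_inclusive(self):
        config = mb.Config()
        ok = self.make_metabolon(2, 2, 2)
        assert mb.filter_metabolons([ok], config) == [ok]

    def test_single_gene_metabolon_discarded(self):
        assert mb.filter_metabolons([self.make_metabolon(1, 3, 3)], mb.Config()) == []

    def test_permissive_thresholds_keep_everything(self):
        config = mb.Config(min_genes=1, min_rxns=1, min_known=1)
        ms = [self.make_metabolon(1, 1, 1), self.make_metabolon(3, 2, 2)]
        assert mb.filter_metabolons(ms, config) == ms


class TestPotential:
    def test_toy_pairs_gap_genes_with_the_gap_reaction(self, toy_result):
        pairs = {
            (a.gene_id, a.reaction_id)
            for a in toy_result.associations
            if a.category == mb.POTENTIAL
        }
        assert pairs == {("gB", "r4"), ("gE", "r4")}

    def test_non_metabolic_gap_gene_is_kept_but_never_proposed(self):
        data = make_toy_data()
        data.genes["org1"]["gB"].non_metabolic = True
        result = mb.run_pipeline(data)
        m = result.metabolons[0]
        assert "gB" in m.gap_genes  # still a connectivity gap
        pairs = {(a.gene_id, a.reaction_id) for a in result.associations
                 if a.category == mb.POTENTIAL}
        assert pairs == {("gE", "r4")}

    def test_gene_known_elsewhere_in_genome_is_not_a_candidate(self):
        # gB carries a Known association to an isolated reaction r9: inside
        # the main metabolon it is a gap, but being annotated elsewhere it
        # cannot be a candidate
        genes = [mb.Gene(f"g{c}", "org1", "chr", i) for i, c in enumerate("ABCDEF")]
        links = [mb.ReactionLink(f"r{i}", f"r{i + 1}", frozenset({f"c{i}"}))
                 for i in range(1, 5)]
        known = [("gA", "r1"), ("gB", "r9"), ("gC", "r2"), ("gD", "r3"),
                 ("gF", "r5")]
        data = mb.assemble_data_graph(
            genes, [f"r{i}" for i in (1, 2, 3, 4, 5, 9)], links,
            [mb.Association("org1", g, r) for g, r in known],
            mb.Config(circular_replicons=False),
        )
        result = mb.run_pipeline(data)
        m = result.metabolons[0]
        assert "gB" in m.gap_genes
        pairs = {(a.gene_id, a.reaction_id) for a in result.associations
                 if a.category == mb.POTENTIAL}
        assert pairs == {("gE", "r4")}

    def test_no_gap_reactions_means_no_potentials(self):
        data = make_toy_data(known=[("gA", "r1"), ("gC", "r2")])
        result = mb.run_pipeline(data)
        assert [a for a in result.associations if a.category == mb.POTENTIAL] == []


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_larger_gaps_never_increase_ccc_count(self, seed):
        from oracles import random_instance
        import numpy as np

        data, _ = random_instance(np.random.default_rng(seed))
        counts = []
        for g in range(0, 5):
            config = mb.Config(g_gene=g, g_rxn=g, min_genes=1, min_rxns=1,
                               min_known=1)
            closures = mb.prepare_closures(data, config)
            blocks = mb.partition_cccs(
                data.known_by_organism("org1"), closures.gene["org1"],
                closures.reaction,
            )
            counts.append(len(blocks))
        assert counts == sorted(counts, reverse=True)
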