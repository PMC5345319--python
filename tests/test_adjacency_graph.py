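"""Adjacency graph structure, siblings, compatibility, decompositions."""

import pytest
from hypothesis import given, strategies as st

import dcjdup as d
from dcjdup.adjacency_graph import STRAIGHT, CROSSED, Cycle, decomposition_from_matching
from dcjdup.genome_core import GeneExtremity

from conftest import random_pairs


class TestGraphStructure:
    def test_seven_gene_pair_counts(self, inconsistency_pair):
        # a x5 and b x2 per genome: 25+25 head/tail a-edges, 4+4 b-edges, 4 capping
        g = d.build_adjacency_graph(*inconsistency_pair)
        assert g.num_vertices == 16
        assert g.num_edges == 62

    def test_worked_pair_vertex_count(self, worked_pair):
        g = d.build_adjacency_graph(*worked_pair)
        assert g.num_vertices == 2 * (11 + 1)

    def test_duplicate_free_edge_count_is_2n_plus_4(self):
        a = d.parse_genome(">A\na b c d e $")
        b = d.parse_genome(">B\n-c a e -b d $")
        g = d.build_adjacency_graph(a, b)
        assert g.num_edges == 2 * 5 + 4

    def test_edge_count_bound(self):
        for a, b in random_pairs(seed=5, count=20):
            g = d.build_adjacency_graph(a, b)
            k = d.occ(a)
            n = len(a)
            assert g.num_vertices == 2 * (n + 1)
            assert g.num_edges <= 2 * k * n + 4

    def test_unbalanced_input_rejected(self):
        with pytest.raises(d.GenomeError):
            d.build_adjacency_graph(d.parse_genome(">A\na a $"), d.parse_genome(">B\na b $"))


class TestSiblings:
    def test_sibling_is_opposite_end_same_occurrences(self, inconsistency_pair):
        g = d.build_adjacency_graph(*inconsistency_pair)
        e = g.edge_by_extremities[(GeneExtremity("a", 1, "h"), GeneExtremity("a", 2, "h"))]
        sib = g.sibling(e)
        assert (sib.a_ext, sib.b_ext) == (GeneExtremity("a", 1, "t"), GeneExtremity("a", 2, "t"))
        assert g.sibling(sib) == e

    def test_telomere_edges_have_no_sibling(self, inconsistency_pair):
        g = d.build_adjacency_graph(*inconsistency_pair)
        tel_edge = next(e for e in g.edges if e.is_telomeric)
        with pytest.raises(d.GenomeError):
            g.sibling(tel_edge)

    def test_sibling_pairs_partition_gene_edges_when_duplicate_free(self):
        for a, b in random_pairs(seed=9, count=10, max_occ=1):
            g = d.build_adjacency_graph(a, b)
            gene_edges = [e for e in g.edges if not e.is_telomeric]
            paired = set()
            for e in gene_edges:
                sib = g.sibling(e)
                assert sib != e
                paired.add(frozenset({e.eid, sib.eid}))
            assert len(paired) == len(gene_edges) // 2


@pytest.fixture(scope="module")
def graph(inconsistency_pair):
    return d.build_adjacency_graph(*inconsistency_pair)


class TestCompatibility:
    def edge(self, graph, fam, i, j, end):
        return graph.edge_by_extremities[(GeneExtremity(fam, i, end), GeneExtremity(fam, j, end))]

    def test_siblings_are_compatible(self, graph):
        e = self.edge(graph, "a", 1, 1, "h")
        assert d.compatible(e, graph.sibling(e))

    def test_conflicting_partners_are_incompatible(self, graph):
        e = self.edge(graph, "a", 1, 1, "h")
        f = self.edge(graph, "a", 1, 2, "t")  # a1 of A paired with both a1 and a2 of B
        assert not d.compatible(e, f)
        assert not d.compatible(f, e)  # symmetric

    def test_distinct_occurrences_and_families_are_compatible(self, graph):
        e = self.edge(graph, "a", 1, 1, "h")
        assert d.compatible(e, self.edge(graph, "a", 2, 2, "t"))
        assert d.compatible(e, self.edge(graph, "b", 1, 1, "t"))

    def test_telomere_edge_rules(self, graph):
        tels = [e for e in graph.edges if e.is_telomeric]
        by_sides = {(e.a_ext.side, e.b_ext.side): e for e in tels}
        assert d.compatible(by_sides[("L", "L")], by_sides[("R", "R")])
        assert not d.compatible(by_sides[("L", "L")], by_sides[("L", "R")])
        assert d.compatible(by_sides[("L", "L")], self.edge(graph, "a", 1, 1, "h"))


class TestConsistency:
    def test_conflicting_two_cycles_are_jointly_inconsistent(self, inconsistency_pair):
        # pair a1-a1 on the head side but a1-a2 on the tail side via 2-cycles
        a, b = inconsistency_pair
        g = d.build_adjacency_graph(a, b)
        d1 = decomposition_from_matching(
            g, {("a", 1): 1, ("a", 2): 2, ("a", 3): 3, ("a", 4): 4, ("a", 5): 5,
                ("b", 1): 1, ("b", 2): 2}, STRAIGHT)
        d2 = decomposition_from_matching(
            g, {("a", 1): 2, ("a", 2): 1, ("a", 3): 3, ("a", 4): 4, ("a", 5): 5,
                ("b", 1): 1, ("b", 2): 2}, STRAIGHT)
        assert d.is_consistent(d1.cycles) and d.is_consistent(d2.cycles)
        assert not d.is_consistent(d1.cycles + d2.cycles)

    def test_single_sibling_closed_two_cycle_is_consistent(self):
        a = d.Genome.from_sequence([("a", 1)], topology="circular")
        g = d.build_adjacency_graph(a, a)
        dec = decomposition_from_matching(g, {("a", 1): 1}, None)
        assert d.is_consistent(dec.cycles)
        assert dec.cycles[0].length == 2


class TestDecompositions:
    def test_matching_induced_decomposition_validates(self):
        for a, b in random_pairs(seed=21, count=10):
            g = d.build_adjacency_graph(a, b)
            bij = {(fam, i): i for fam, m in a.family_counts().items() for i in range(1, m + 1)}
            for tm in (STRAIGHT, CROSSED):
                dec = decomposition_from_matching(g, bij, tm)
                d.validate_decomposition(dec)
                assert dec.occurrence_bijection == bij

    def test_distance_formula_on_worked_pair(self, worked_pair):
        dist, best = d.dcj_exact_small(*worked_pair)
        assert best.n == 12
        assert d.distance_of(best) == 12 - best.num_cycles == 6

    def test_identity_all_two_cycles_distance_zero(self):
        a = d.parse_genome(">A\na b c $")
        g = d.build_adjacency_graph(a, a)
        dec = decomposition_from_matching(g, {("a", 1): 1, ("b", 1): 1, ("c", 1): 1}, STRAIGHT)
        assert all(c.length == 2 for c in dec.cycles)
        assert d.distance_of(dec) == 0

    def test_validator_rejects_partial_cover(self, worked_pair):
        _, best = d.dcj_exact_small(*worked_pair)
        broken = d.Decomposition(best.graph, best.cycles[:-1])
        with pytest.raises(d.DecompositionError):
            d.validate_decomposition(broken)
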