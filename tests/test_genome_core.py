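"""Genome data model: parsing, adjacencies, strings, balance, the DCJ operation."""

import pytest
from hypothesis import given, strategies as st

import dcjdup as d
from dcjdup.genome_core import Adjacency, GeneExtremity, Telomere

from conftest import FIG_DUP_A


FAMILIES = st.sampled_from(["a", "b", "c", "d", "e"])
SYMBOLS = st.tuples(FAMILIES, st.sampled_from([1, -1]))
GENOME_SEQ = st.lists(SYMBOLS, min_size=1, max_size=12)
TOPOLOGY = st.sampled_from(["linear", "circular"])


class TestParsing:
    def test_worked_pair_parses_with_occurrence_numbering(self):
        g = d.parse_genome(FIG_DUP_A)
        assert len(g) == 11 and g.is_linear and g.name == "A"
        assert g.family_counts() == {
            "a": 2, "b": 2, "c": 1, "d": 1, "e": 1, "f": 1, "g": 1, "h": 1, "i": 1
        }
        # left-to-right numbering of the duplicated families
        a_genes = [x for x in g.genes if x.family == "a"]
        assert [x.occurrence for x in a_genes] == [1, 2]
        assert [x.orient for x in a_genes] == [1, -1]

    def test_singleton_and_circular_numbering(self):
        assert len(d.parse_genome(">X\na $")) == 1
        g = d.parse_genome(">Y\na b a @")
        assert g.is_circular
        assert [x.occurrence for x in g.genes if x.family == "a"] == [1, 2]

    @pytest.mark.parametrize(
        "text, fragment",
        [
            (">A\n$", "empty"),
            (">A\na b", "terminator"),
            (">A\n- b $", "malformed"),
            (">A\na --b $", "malformed"),
        ],
    )
    def test_parse_errors_name_the_problem(self, text, fragment):
        with pytest.raises(d.ParseError, match=fragment):
            d.parse_genome(text)

    def test_comment_lines_are_skipped(self):
        g = d.parse_genome("# a comment\n>A\na -b $")
        assert g.signed_symbols() == (("a", 1), ("b", -1))

    @given(seq=GENOME_SEQ, topo=TOPOLOGY)
    def test_write_parse_round_trip(self, seq, topo):
        g = d.Genome.from_sequence(seq, topology=topo, name="rt")
        assert d.parse_genome(d.write_genome(g)) == g


class TestAdjacencies:
    def test_worked_adjacency_set(self):
        g = d.parse_genome(">A\nc -a d b -a c $")
        got = d.adjacencies(g)
        H, T = "h", "t"
        expected = (
            Adjacency(Telomere("L"), GeneExtremity("c", 1, T)),
            Adjacency(GeneExtremity("c", 1, H), GeneExtremity("a", 1, H)),
            Adjacency(GeneExtremity("a", 1, T), GeneExtremity("d", 1, T)),
            Adjacency(GeneExtremity("d", 1, H), GeneExtremity("b", 1, T)),
            Adjacency(GeneExtremity("b", 1, H), GeneExtremity("a", 2, H)),
            Adjacency(GeneExtremity("a", 2, T), GeneExtremity("c", 2, T)),
            Adjacency(GeneExtremity("c", 2, H), Telomere("R")),
        )
        assert got == expected

    def test_degenerate_shapes(self):
        one_circ = d.Genome.from_sequence([("a", 1)], topology="circular")
        (adj,) = d.adjacencies(one_circ)
        assert set(adj.extremities()) == {GeneExtremity("a", 1, "h"), GeneExtremity("a", 1, "t")}
        one_lin = d.Genome.from_sequence([("a", 1)])
        assert [a.is_telomeric() for a in d.adjacencies(one_lin)] == [True, True]
        with pytest.raises(d.GenomeError):
            d.adjacencies(d.Genome(()))

    @given(seq=GENOME_SEQ, topo=TOPOLOGY)
    def test_adjacency_count_formula(self, seq, topo):
        g = d.Genome.from_sequence(seq, topology=topo)
        expected = len(g) + 1 if topo == "linear" else len(g)
        adj = d.adjacencies(g)
        assert len(adj) == expected
        used = [e for a in adj for e in a.extremities() if isinstance(e, GeneExtremity)]
        assert len(used) == len(set(used)) == 2 * len(g)


class TestStringsAndBalance:
    def test_index_free_string_strips_indices(self):
        g = d.parse_genome(">A\nc -a d b c c $")
        assert d.index_free_string(g) == (
            ("c", 1), ("a", -1), ("d", 1), ("b", 1), ("c", 1), ("c", 1)
        )
        with pytest.raises(d.GenomeError):
            d.index_free_string(d.parse_genome(">A\na b @"))

    def test_occ_is_max_multiplicity(self):
        assert d.occ(d.parse_genome(">A\nc -a d b c c $")) == 3
        assert d.occ(d.parse_genome(">A\na b c $")) == 1
        assert d.occ(d.parse_genome(">A\na a a a $")) == 4
        with pytest.raises(d.GenomeError):
            d.occ(d.Genome(()))

    def test_balanced_examples(self):
        a = d.parse_genome(">A\nc -a d b c c $")
        b = d.parse_genome(">B\na c -c -b d c $")
        assert d.is_balanced(a, b)
        assert d.is_balanced(a, a)
        assert not d.is_balanced(d.parse_genome(">A\na $"), d.parse_genome(">B\nb $"))
        assert not d.is_balanced(a, d.parse_genome(">B\na c -c -b d c @"))


class TestApplyDcj:
    def test_inversion_worked_example(self):
        g = d.parse_genome(">A\nc -a d b -a c $")
        out = d.apply_dcj(g, 1, 3, "swap-keep")
        assert out.signed_symbols() == (
            ("c", 1), ("d", -1), ("a", 1), ("b", 1), ("a", -1), ("c", 1)
        )

    def test_inversion_is_an_involution(self):
        g = d.parse_genome(">A\nc -a d b -a c $")
        out = d.apply_dcj(d.apply_dcj(g, 2, 3), 2, 3)
        assert out.signed_symbols() == g.signed_symbols()

    @given(seq=GENOME_SEQ, data=st.data())
    def test_dcj_preserves_gene_content(self, seq, data):
        g = d.Genome.from_sequence(seq)
        n = len(d.adjacencies(g))
        i = data.draw(st.integers(0, n - 1))
        j = data.draw(st.integers(0, n - 1).filter(lambda x: x != i))
        out = d.apply_dcj(g, i, j)
        assert out.family_counts() == g.family_counts()
        assert len(out) == len(g)

    def test_identical_cuts_rejected(self):
        g = d.parse_genome(">A\na b $")
        with pytest.raises(d.GenomeError):
            d.apply_dcj(g, 1, 1)

    def test_cross_rejoin_excision_is_rejected(self):
        g = d.parse_genome(">A\nc -a d b -a c $")
        with pytest.raises(d.GenomeError, match="unichromosomal"):
            d.apply_dcj(g, 1, 3, "swap-cross")

    def test_cross_rejoin_of_telomeric_cuts_circularizes(self):
        g = d.parse_genome(">A\na b c $")
        out = d.apply_dcj(g, 0, 3, "swap-cross")
        assert out.is_circular and out.family_counts() == g.family_counts()
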