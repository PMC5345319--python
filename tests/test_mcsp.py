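"""Common string partitions: normalization, buckets, mapping, greedy partitioner."""

import pytest
from hypothesis import given, strategies as st

import dcjdup as d
from dcjdup.mcsp import Block, bucket_by_length, substring_mapping

from conftest import signed


SYMBOLS = st.tuples(st.sampled_from(["a", "b", "c"]), st.sampled_from([1, -1]))
SIGNED_STRINGS = st.lists(SYMBOLS, min_size=1, max_size=8).map(tuple)


class TestNormalization:
    def test_reversed_ba_normalizes_to_ab(self):
        vals = d.symbol_values(signed("a b"))
        assert d.normalize_block(signed("b- a-"), vals) == signed("a b")

    def test_already_minimal_is_unchanged(self):
        vals = d.symbol_values(signed("a b"))
        assert d.normalize_block(signed("a b"), vals) == signed("a b")

    def test_forward_form_wins_over_reversal(self):
        # v(g) < v(g-), so aba precedes its signed reversal -a -b -a
        vals = d.symbol_values(signed("a b"))
        assert d.normalize_block(signed("a- b- a-"), vals) == signed("a b a")

    @given(s=SIGNED_STRINGS)
    def test_idempotent_and_reversal_invariant(self, s):
        vals = d.symbol_values(s)
        n = d.normalize_block(s, vals)
        assert d.normalize_block(n, vals) == n
        assert d.normalize_block(d.signed_reverse(s), vals) == n


def _blocks(source, texts):
    out = []
    pos = 0
    for text in texts:
        content = signed(text)
        out.append(Block(source, pos, content))
        pos += len(content)
    return out


@pytest.fixture(scope="module")
def preprocessing_example():
    """The printed preprocessing instance: five blocks per side, lengths 3 and 4."""
    a_blocks = _blocks("A", ["a b a", "b b b", "b- a- b a", "a- b- a-", "a b b"])
    b_blocks = _blocks("B", ["b- b- b-", "a b a", "a b a", "a b b", "b- a- b a"])
    vals = d.symbol_values(signed("a b"))
    return a_blocks, b_blocks, vals


class TestBucketsAndMapping:
    def test_bucket_sizes_of_preprocessing_example(self, preprocessing_example):
        a_blocks, b_blocks, vals = preprocessing_example
        buckets = d.bucket_by_length(a_blocks, b_blocks, vals)
        assert sorted(buckets) == [3, 4]
        assert len(buckets[3].entries) == 8
        assert len(buckets[4].entries) == 2
        total = sum(l * len(b.entries) for l, b in buckets.items())
        assert total == sum(b.length for b in a_blocks + b_blocks)

    def test_mapping_pairs_equal_normalized_strings(self, preprocessing_example):
        a_blocks, b_blocks, vals = preprocessing_example
        buckets = d.bucket_by_length(a_blocks, b_blocks, vals)
        pairs3 = d.substring_mapping(buckets[3], vals)
        # aba, aba (one the reversal -a -b -a), bbb (vs -b -b -b), abb all pair up
        assert len(pairs3) == 4
        for a_blk, b_blk in pairs3:
            assert d.normalize_block(a_blk.content, vals) == d.normalize_block(b_blk.content, vals)
        assert len({a for a, _ in pairs3}) == 4 and len({b for _, b in pairs3}) == 4
        pairs4 = d.substring_mapping(buckets[4], vals)
        assert len(pairs4) == 1

    def test_single_pair_and_no_match_buckets(self):
        vals = d.symbol_values(signed("a b"))
        bucket = d.bucket_by_length(_blocks("A", ["a b"]), _blocks("B", ["b- a-"]), vals)[2]
        assert len(d.substring_mapping(bucket, vals)) == 1
        disjoint = d.bucket_by_length(_blocks("A", ["a a"]), _blocks("B", ["a b"]), vals)[2]
        assert d.substring_mapping(disjoint, vals) == []


class TestGreedyPartition:
    def test_worked_mcsp_pair_yields_printed_partition(self):
        s, t = signed("b- a- a a b"), signed("a b a b a")
        cp = d.mcsp_approx(s, t)
        assert cp.size == 3
        assert [b.content for b in cp.a_blocks] == [signed("b- a-"), signed("a"), signed("a b")]
        assert [b.content for b in cp.b_blocks] == [signed("a b"), signed("a b"), signed("a")]

    def test_identical_strings_single_block(self):
        s = signed("a b- c a")
        cp = d.mcsp_approx(s, s)
        assert cp.size == 1 and not cp.pair_reversed(*cp.pairs[0])

    def test_unbalanced_strings_rejected(self):
        with pytest.raises(d.PartitionError):
            d.mcsp_approx(signed("a a"), signed("a b"))

    @given(s=SIGNED_STRINGS, data=st.data())
    def test_valid_partition_and_oracle_lower_bound(self, s, data):
        # t = a random reshuffle of s's families with random signs
        fams = [f for f, _ in s]
        perm = data.draw(st.permutations(range(len(s))))
        t = tuple((fams[i], data.draw(st.sampled_from([1, -1]))) for i in perm)
        cp = d.mcsp_approx(s, t)
        d.validate_common_partition(cp)
        assert cp.size >= d.mcsp_exact_small(s, t, cap=8) or len(s) > 8
        if len(s) <= 8:
            assert cp.size >= d.mcsp_exact_small(s, t, cap=8)


class TestPreservedAdjacencyCycles:
    def test_mapped_ab_block_gives_one_two_cycle(self):
        a = d.parse_genome(">A\na b c $")
        b = d.parse_genome(">B\nc a b $")
        graph = d.build_adjacency_graph(a, b)
        cp = d.mcsp_approx(d.index_free_string(a), d.index_free_string(b))
        c2 = d.preserved_adjacency_cycles(cp, graph)
        # blocks [ab][c] vs [c][ab]: exactly the preserved adjacency head(a)-tail(b)
        pairings = {e.pairing() for cyc in c2 for e in cyc.edges}
        assert len(c2) == 1 and all(c.length == 2 for c in c2)
        assert pairings == {("a", 1, 1), ("b", 1, 1)}

    def test_identity_gives_length_minus_one_cycles(self):
        g = d.parse_genome(">A\na b c d e $")
        graph = d.build_adjacency_graph(g, g)
        cp = d.mcsp_approx(d.index_free_string(g), d.index_free_string(g))
        c2 = d.preserved_adjacency_cycles(cp, graph)
        assert len(c2) == len(g) - 1

    def test_all_singleton_blocks_give_empty_c2(self):
        a = d.parse_genome(">A\na b c $")
        b = d.parse_genome(">B\nb c a $")  # blocks may still merge: force singletons
        s, t = d.index_free_string(a), d.index_free_string(b)
        cp = d.mcsp_approx(s, t)
        if all(blk.length == 1 for blk in cp.a_blocks):
            graph = d.build_adjacency_graph(a, b)
            assert d.preserved_adjacency_cycles(cp, graph) == []

    def test_c2_count_matches_block_length_formula(self):
        from conftest import random_pairs

        for a, b in random_pairs(seed=33, count=15):
            graph = d.build_adjacency_graph(a, b)
            cp = d.mcsp_approx(d.index_free_string(a), d.index_free_string(b))
            c2 = d.preserved_adjacency_cycles(cp, graph)
            expected = sum(blk.length - 1 for blk, _ in cp.pairs)
            assert len(c2) == expected
            assert all(c.length == 2 for c in c2)
            assert d.is_consistent(c2)
            # adding the siblings of every chosen edge keeps the set compatible
            siblings = [
                d.Cycle((graph.sibling(e), graph.sibling(e)))
                for c in c2
                for e in c.edges
                if not e.is_telomeric
            ]
            assert d.is_consistent(list(c2) + siblings)
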