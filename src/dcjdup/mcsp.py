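"""Common string partitions of index-free genome strings.

Two balanced signed strings (the gene sequences of the two genomes with
telomeres and occurrence indices stripped) admit a *common partition*: a
pair of block sequences tiling each string such that the blocks of one
side are a permutation of the blocks of the other, where a block also
matches its signed reversal.  Minimising the number of blocks (the
minimum common string partition, MCSP) minimises breakpoints; every
block of length ``l`` contributes ``l - 1`` preserved adjacencies, each
realized as a length-2 cycle of the adjacency graph.

The default partitioner is an iterative greedy extraction of a longest
common block (up to signed reversal, leftmost-first tie-breaks).  It
always yields a valid common partition; no approximation factor is
asserted of it beyond validation against the exact brute-force oracle
in the test-suite.  Block pairing between the two sides uses the
normalize / bucket-by-length / bucket-splitting pipeline, which runs in
time proportional to the total symbol count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome_core import GenomeError, Genome, SignedSymbol, GeneExtremity, left_extremity, right_extremity
from .adjacency_graph import AdjacencyGraph, Cycle


class PartitionError(GenomeError):
    """An invalid common partition."""


SignedString = tuple[SignedSymbol, ...]


def signed_reverse(s: Sequence[SignedSymbol]) -> SignedString:
    """Reversal with orientation flip (reading the block from the other strand)."""
    return tuple((fam, -orient) for fam, orient in reversed(s))


def symbol_values(*strings: Sequence[SignedSymbol]) -> dict[str, int]:
    """Family -> value map, first-appearance order, values 1..|alphabet|."""
    values: dict[str, int] = {}
    for s in strings:
        for fam, _ in s:
            if fam not in values:
                values[fam] = len(values) + 1
    return values


def _value_key(s: Sequence[SignedSymbol], values: dict[str, int]) -> tuple[int, ...]:
    n = len(values)
    return tuple(values[fam] + (0 if orient > 0 else n) for fam, orient in s)


def normalize_block(s: Sequence[SignedSymbol], values: dict[str, int]) -> SignedString:
    """The lexicographically smaller of a block and its signed reversal.

    Forward symbols order before reversed ones (value ``v(g)`` vs
    ``v(g) + n``), so e.g. the reversal of ``ba`` normalizes to ``ab``.
    Idempotent and invariant under signed reversal of the input.
    """
    s = tuple(s)
    r = signed_reverse(s)
    return s if _value_key(s, values) <= _value_key(r, values) else r


@dataclass(frozen=True)
class Block:
    """A block of one side of a common partition."""

    source: str  # "A" or "B"
    start: int  # 0-based position in the index-free string
    content: SignedString

    @property
    def length(self) -> int:
        return len(self.content)


@dataclass(frozen=True)
class BucketEntry:
    block: Block
    normalized: SignedString

    @property
    def origin(self) -> str:
        return self.block.source


@dataclass(frozen=True)
class NormalizedBucket:
    """All normalized blocks of one length, both origins mixed."""

    length: int
    entries: tuple[BucketEntry, ...]


def bucket_by_length(
    a_blocks: Sequence[Block],
    b_blocks: Sequence[Block],
    values: dict[str, int],
) -> dict[int, NormalizedBucket]:
    """Gather normalized blocks of equal length into buckets, keyed by length."""
    grouped: dict[int, list[BucketEntry]] = {}
    for block in list(a_blocks) + list(b_blocks):
        entry = BucketEntry(block, normalize_block(block.content, values))
        grouped.setdefault(block.length, []).append(entry)
    return {l: NormalizedBucket(l, tuple(entries)) for l, entries in grouped.items()}


def substring_mapping(
    bucket: NormalizedBucket, values: dict[str, int]
) -> list[tuple[Block, Block]]:
    """Pair A-origin blocks with identical B-origin blocks of one bucket.

    Splits the bucket symbol position by symbol position: after pass
    ``i`` every group holds strings equal on their first ``i`` symbols,
    so the final groups hold equal strings.  Within a group, A and B
    entries are paired in order of first appearance.  The pairing is a
    partial bijection; for blocks of a valid common partition it is
    total on the A side.
    """
    groups: list[list[BucketEntry]] = [list(bucket.entries)]
    for i in range(bucket.length):
        next_groups: list[list[BucketEntry]] = []
        for group in groups:
            split: dict[int, list[BucketEntry]] = {}
            for entry in group:
                fam, orient = entry.normalized[i]
                v = values[fam] + (0 if orient > 0 else len(values))
                split.setdefault(v, []).append(entry)
            next_groups.extend(split.values())
        groups = next_groups
    pairs: list[tuple[Block, Block]] = []
    for group in groups:
        a_entries = [e for e in group if e.origin == "A"]
        b_entries = [e for e in group if e.origin == "B"]
        pairs.extend((ea.block, eb.block) for ea, eb in zip(a_entries, b_entries))
    return pairs


@dataclass(frozen=True)
class CommonPartition:
    """Paired block partitions of two balanced signed strings."""

    s: SignedString
    t: SignedString
    a_blocks: tuple[Block, ...]  # tile ``s`` in order of start
    b_blocks: tuple[Block, ...]  # tile ``t`` in order of start
    pairs: tuple[tuple[Block, Block], ...]

    @property
    def size(self) -> int:
        return len(self.a_blocks)

    def pair_reversed(self, a_block: Block, b_block: Block) -> bool:
        """Whether the matched pair is related by signed reversal."""
        if a_block.content == b_block.content:
            return False
        if a_block.content == signed_reverse(b_block.content):
            return True
        raise PartitionError("paired blocks are not equal up to signed reversal")

    def to_record(self) -> dict:
        return {
            "size": self.size,
            "a_blocks": [[b.start, [f"{'-' if o < 0 else ''}{fam}" for fam, o in b.content]] for b in self.a_blocks],
            "b_blocks": [[b.start, [f"{'-' if o < 0 else ''}{fam}" for fam, o in b.content]] for b in self.b_blocks],
            "pairs": [[a.start, b.start] for a, b in self.pairs],
        }


def validate_common_partition(cp: CommonPartition) -> None:
    """Raise :class:`PartitionError` unless the partition is valid."""
    for string, blocks, label in ((cp.s, cp.a_blocks, "A"), (cp.t, cp.b_blocks, "B")):
        pos = 0
        for b in blocks:
            if b.start != pos or string[pos : pos + b.length] != b.content:
                raise PartitionError(f"blocks of side {label} do not tile the string")
            pos += b.length
        if pos != len(string):
            raise PartitionError(f"blocks of side {label} do not cover the string")
    if len(cp.a_blocks) != len(cp.b_blocks):
        raise PartitionError("the two sides have different numbers of blocks")
    if len(cp.pairs) != len(cp.a_blocks):
        raise PartitionError("pairing is not total")
    if set(a for a, _ in cp.pairs) != set(cp.a_blocks) or set(b for _, b in cp.pairs) != set(cp.b_blocks):
        raise PartitionError("pairing is not a bijection between the block sequences")
    for a, b in cp.pairs:
        cp.pair_reversed(a, b)  # raises if contents do not match


def _free_runs(free: Sequence[bool]) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(free):
        if free[i]:
            j = i
            while j < len(free) and free[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def mcsp_approx(
    s: Sequence[SignedSymbol],
    t: Sequence[SignedSymbol],
    strategy: str = "greedy-longest",
) -> CommonPartition:
    """A valid common partition of balanced signed strings *s* and *t*.

    The default (and only built-in) strategy extracts a longest common
    block, up to signed reversal, repeatedly; ties break leftmost in *s*
    then leftmost in *t*.  The result is validated before it is
    returned.
    """
    if strategy != "greedy-longest":
        raise PartitionError(f"unknown partition strategy {strategy!r}")
    s, t = tuple(s), tuple(t)
    from collections import Counter

    if Counter(fam for fam, _ in s) != Counter(fam for fam, _ in t):
        raise PartitionError("strings are not balanced")
    values = symbol_values(s, t)
    free_s = [True] * len(s)
    free_t = [True] * len(t)
    picks: list[tuple[int, int, int]] = []  # (s_start, t_start, length)

    def find_match(length: int) -> Optional[tuple[int, int]]:
        tmap: dict[SignedString, int] = {}
        for lo, hi in _free_runs(free_t):
            for start in range(lo, hi - length + 1):
                key = normalize_block(t[start : start + length], values)
                tmap.setdefault(key, start)
        for lo, hi in _free_runs(free_s):
            for start in range(lo, hi - length + 1):
                key = normalize_block(s[start : start + length], values)
                if key in tmap:
                    return start, tmap[key]
        return None

    while any(free_s):
        hi = min(
            max((b - a for a, b in _free_runs(free_s)), default=0),
            max((b - a for a, b in _free_runs(free_t)), default=0),
        )
        lo = 1
        best = find_match(1)
        if best is None:
            raise PartitionError("no common symbol among free positions (unbalanced input?)")
        # binary search the largest length with a common free block
        while lo < hi:
            mid = (lo + hi + 1) // 2
            cand = find_match(mid)
            if cand is None:
                hi = mid - 1
            else:
                lo = mid
                best = cand
        s_start, t_start = best
        picks.append((s_start, t_start, lo))
        for p in range(s_start, s_start + lo):
            free_s[p] = False
        for p in range(t_start, t_start + lo):
            free_t[p] = False

    a_blocks = tuple(
        Block("A", st, s[st : st + ln]) for st, _, ln in sorted(picks)
    )
    b_blocks = tuple(
        Block("B", tt, t[tt : tt + ln]) for _, tt, ln in sorted(picks, key=lambda p: p[1])
    )
    buckets = bucket_by_length(a_blocks, b_blocks, values)
    pairs: list[tuple[Block, Block]] = []
    for length in sorted(buckets):
        pairs.extend(substring_mapping(buckets[length], values))
    cp = CommonPartition(s, t, a_blocks, b_blocks, tuple(pairs))
    validate_common_partition(cp)
    return cp


def preserved_adjacency_cycles(cp: CommonPartition, graph: AdjacencyGraph) -> list[Cycle]:
    """The set C2 of length-2 cycles induced by a common partition.

    Each mapped block pair of length ``l`` contributes its ``l - 1``
    interior preserved adjacencies; each is realized as the pair of
    parallel edges between the corresponding adjacency-graph vertices.
    Only linear genomes carry index-free strings, so the graph must stem
    from linear genomes whose strings equal ``cp.s`` and ``cp.t``.
    """
    a_genome = graph.a_genome
    b_genome = graph.b_genome
    if a_genome.signed_symbols() != cp.s or b_genome.signed_symbols() != cp.t:
        raise PartitionError("partition does not belong to the graph's genomes")
    cycles: list[Cycle] = []
    for a_block, b_block in cp.pairs:
        l = a_block.length
        if l == 1:
            continue
        reversed_pair = cp.pair_reversed(a_block, b_block)
        for o in range(l - 1):
            pa = a_block.start + o
            # adjacency between genes pa and pa+1 sits at vertex index pa+1
            a_vertex = pa + 1
            if not reversed_pair:
                pb = b_block.start + o
                e1_b = right_extremity(b_genome.genes[pb])
                e2_b = left_extremity(b_genome.genes[pb + 1])
            else:
                pb = b_block.start + (l - 1 - o)
                e1_b = left_extremity(b_genome.genes[pb])
                e2_b = right_extremity(b_genome.genes[pb - 1])
            e1_a = right_extremity(a_genome.genes[pa])
            e2_a = left_extremity(a_genome.genes[pa + 1])
            try:
                edge1 = graph.edge_by_extremities[(e1_a, e1_b)]
                edge2 = graph.edge_by_extremities[(e2_a, e2_b)]
            except KeyError as exc:  # pragma: no cover - defensive
                raise PartitionError(f"partition inconsistent with graph: {exc}") from exc
            if edge1.a_vertex != a_vertex or edge2.a_vertex != a_vertex or edge1.b_vertex != edge2.b_vertex:
                raise PartitionError("preserved adjacency does not map to a 2-cycle")
            cycles.append(Cycle((edge1, edge2)))
    return cycles
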