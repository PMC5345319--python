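"""Brute-force references for small instances.

The exact DCJ distance of balanced genomes is the minimum of
``n - c_D`` over all consistent decompositions of the adjacency graph.
Every consistent decomposition corresponds to one family-wise matching
of gene occurrences (plus, for linear genomes, one of the two telomere
matchings), so exhaustively enumerating those matchings enumerates the
decompositions.  The enumeration size is the product of the factorials
of the family multiplicities; oracles refuse instances above a cap
instead of ever returning an approximate value.

Also provided: the closed-form duplicate-free distance, an exact
minimum common string partition by enumeration, 2-cycle-maximisation
statistics, and a paper-independent breadth-first search over actual
DCJ operations on adjacency sets.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, deque
from typing import Iterable, Iterator, Optional

from .genome_core import (
    Genome,
    GenomeError,
    SignedSymbol,
    Telomere,
    adjacencies,
    is_balanced,
    occ,
)
from .adjacency_graph import (
    CROSSED,
    STRAIGHT,
    AdjacencyGraph,
    Decomposition,
    all_occurrence_bijections,
    build_adjacency_graph,
    decomposition_from_matching,
)
from .mcsp import normalize_block, symbol_values


class InstanceTooLarge(GenomeError):
    """The brute-force enumeration would exceed its configured cap."""


def _enumeration_size(a: Genome) -> int:
    size = math.prod(math.factorial(m) for m in a.family_counts().values())
    if a.is_linear:
        size *= 2
    return size


def enumerate_decompositions(a: Genome, b: Genome, cap: int = 10**5) -> Iterator[Decomposition]:
    """Yield every consistent decomposition of AG(A, B)."""
    if not is_balanced(a, b):
        raise GenomeError("genomes must be balanced")
    size = _enumeration_size(a)
    if size > cap:
        raise InstanceTooLarge(
            f"instance too large: {size} consistent decompositions exceed the cap {cap}"
        )
    graph = build_adjacency_graph(a, b)
    matchings = (STRAIGHT, CROSSED) if a.is_linear else (None,)
    for bijection in all_occurrence_bijections(a):
        for tm in matchings:
            yield decomposition_from_matching(graph, bijection, tm)


def dcj_exact_small(a: Genome, b: Genome, cap: int = 10**5) -> tuple[int, Decomposition]:
    """Exact DCJ distance (and an optimal decomposition) by enumeration."""
    best: Optional[Decomposition] = None
    for d in enumerate_decompositions(a, b, cap):
        if best is None or d.distance < best.distance:
            best = d
    assert best is not None
    return best.distance, best


def dcj_exact_no_duplicates(a: Genome, b: Genome) -> int:
    """Exact distance ``n - c`` for duplicate-free balanced genomes.

    With a single occurrence per family the occurrence matching is
    forced; for linear genomes the better of the two telomere matchings
    realizes the cycle-maximizing walk.
    """
    if not is_balanced(a, b):
        raise GenomeError("genomes must be balanced")
    if occ(a) != 1:
        raise GenomeError("dcj_exact_no_duplicates requires occ(A) = occ(B) = 1")
    graph = build_adjacency_graph(a, b)
    bijection = {(fam, 1): 1 for fam in a.family_counts()}
    if a.is_linear:
        return min(
            decomposition_from_matching(graph, bijection, tm).distance
            for tm in (STRAIGHT, CROSSED)
        )
    return decomposition_from_matching(graph, bijection, None).distance


def max_c2_and_constrained_min(a: Genome, b: Genome, cap: int = 10**5) -> tuple[int, int]:
    """Best-possible 2-cycle count and the best distance attaining it.

    Over all consistent decompositions: the maximum number of length-2
    cycles, and the minimum ``n - c`` among the decompositions reaching
    that maximum (the best a "maximize 2-cycles first" strategy can do;
    empirically a 2-approximation of the exact distance).
    """
    best_c2 = -1
    best_distance = -1
    for d in enumerate_decompositions(a, b, cap):
        if d.c2 > best_c2:
            best_c2, best_distance = d.c2, d.distance
        elif d.c2 == best_c2 and d.distance < best_distance:
            best_distance = d.distance
    return best_c2, best_distance


# ---------------------------------------------------------------------------
# Exact minimum common string partition
# ---------------------------------------------------------------------------

def mcsp_exact_small(
    s: Iterable[SignedSymbol], t: Iterable[SignedSymbol], cap: int = 12
) -> int:
    """Exact minimum common partition size of balanced signed strings.

    Enumerates split patterns of *s* by increasing block count and
    checks whether *t* tiles with the same block multiset (blocks match
    up to signed reversal).
    """
    s, t = tuple(s), tuple(t)
    if Counter(f for f, _ in s) != Counter(f for f, _ in t):
        raise GenomeError("strings are not balanced")
    if len(s) > cap:
        raise InstanceTooLarge(f"string length {len(s)} exceeds the cap {cap}")
    if not s:
        return 0
    values = symbol_values(s, t)

    def norm(x):
        return normalize_block(x, values)

    def tiles(t_pos: int, blocks: Counter) -> bool:
        if t_pos == len(t):
            return not +blocks
        for length in set(len(b) for b in blocks if blocks[b] > 0):
            if t_pos + length > len(t):
                continue
            key = norm(t[t_pos : t_pos + length])
            if blocks[key] > 0:
                blocks[key] -= 1
                if tiles(t_pos + length, blocks):
                    blocks[key] += 1
                    return True
                blocks[key] += 1
        return False

    L = len(s)
    for m in range(1, L + 1):
        for split in itertools.combinations(range(1, L), m - 1):
            bounds = (0,) + split + (L,)
            blocks = Counter(norm(s[i:j]) for i, j in zip(bounds, bounds[1:]))
            if tiles(0, blocks):
                return m
    return L  # unreachable for balanced strings; all-singletons always tiles


# ---------------------------------------------------------------------------
# BFS over actual DCJ operations (paper-independent cross-check)
# ---------------------------------------------------------------------------

def _adjacency_state(genome: Genome) -> frozenset[frozenset]:
    """Genome as a set of adjacencies; chromosome ends become singletons."""
    state = set()
    for adj in adjacencies(genome):
        exts = [e for e in adj.extremities() if not isinstance(e, Telomere)]
        state.add(frozenset(exts))
    return frozenset(state)


def _dcj_neighbors(state: frozenset[frozenset]) -> Iterator[frozenset[frozenset]]:
    adj_list = list(state)
    for idx, p in enumerate(adj_list):
        if len(p) == 2:  # cut one adjacency into two chromosome ends
            p1, p2 = sorted(p, key=repr)
            yield state - {p} | {frozenset([p1]), frozenset([p2])}
    for p, q in itertools.combinations(adj_list, 2):
        if len(p) == 2 and len(q) == 2:
            p1, p2 = sorted(p, key=repr)
            q1, q2 = sorted(q, key=repr)
            yield state - {p, q} | {frozenset([p1, q1]), frozenset([p2, q2])}
            yield state - {p, q} | {frozenset([p1, q2]), frozenset([p2, q1])}
        elif len(p) == 2 and len(q) == 1:
            (p1, p2), (q1,) = sorted(p, key=repr), tuple(q)
            yield state - {p, q} | {frozenset([p1, q1]), frozenset([p2])}
            yield state - {p, q} | {frozenset([p2, q1]), frozenset([p1])}
        elif len(p) == 1 and len(q) == 2:
            (p1,), (q1, q2) = tuple(p), sorted(q, key=repr)
            yield state - {p, q} | {frozenset([q1, p1]), frozenset([q2])}
            yield state - {p, q} | {frozenset([q2, p1]), frozenset([q1])}
        else:
            (p1,), (q1,) = tuple(p), tuple(q)
            yield state - {p, q} | {frozenset([p1, q1])}


def bfs_dcj_distance(a: Genome, b: Genome, max_genes: int = 6, max_depth: int = 12) -> int:
    """Exact DCJ distance by breadth-first search over DCJ operations.

    Explores all genomes (multichromosomal intermediates included, as
    the DCJ model allows) reachable from *A*, until reaching any genome
    of the equivalence class of *B*.  Only for tiny instances.
    """
    if not is_balanced(a, b):
        raise GenomeError("genomes must be balanced")
    if len(a) > max_genes:
        raise InstanceTooLarge(f"BFS oracle limited to {max_genes} genes")
    targets = set()
    for bijection in all_occurrence_bijections(b):
        relabeled = Genome(
            tuple(
                type(g)(g.family, g.orient, bijection[(g.family, g.occurrence)])
                for g in b.genes
            ),
            b.topology,
            b.name,
        )
        targets.add(_adjacency_state(relabeled))
    start = _adjacency_state(a)
    if start in targets:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, depth = frontier.popleft()
        if depth >= max_depth:
            continue
        for nxt in _dcj_neighbors(state):
            if nxt in seen:
                continue
            if nxt in targets:
                return depth + 1
            seen.add(nxt)
            frontier.append((nxt, depth + 1))
    raise GenomeError(f"no DCJ scenario within depth {max_depth}")
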