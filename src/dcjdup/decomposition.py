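"""Consistent decomposition of the adjacency graph: the O(k) approximation.

The pipeline for two balanced linear genomes with duplication bound
``k = occ``:

1. build AG(A, B);
2. compute a common partition of the index-free strings and collect the
   set ``C2`` of length-2 cycles reflecting its preserved adjacencies;
3. remove vertices covered by ``C2`` and edges incompatible with its
   edges;
4. repeatedly close consistent cycles in the remaining graph, removing
   edges incompatible with every chosen edge, until the graph is empty;
5. return ``D = C2 ∪ C_>`` with distance ``d_D = n - c_D``.

The distance is an upper bound on the exact DCJ distance (Theorem-level
contract: an O(k) factor when the partition stage is an O(k)
approximation of the minimum common string partition).  Circular
genomes are handled by linearizing both genomes at a low-multiplicity
anchor family and keeping the best of the anchored runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .genome_core import (
    CIRCULAR,
    FORWARD,
    Extremity,
    GeneExtremity,
    Genome,
    GenomeError,
    SignedSymbol,
    Telomere,
    index_free_string,
    is_balanced,
    occ,
)
from .adjacency_graph import (
    AdjacencyGraph,
    Cycle,
    Decomposition,
    DecompositionError,
    Edge,
    build_adjacency_graph,
    validate_decomposition,
)
from .mcsp import CommonPartition, mcsp_approx, preserved_adjacency_cycles

STRATEGIES = ("greedy", "first", "random")


class RemainingGraph:
    """Mutable view of AG(A, B) during Steps 3-4 of the decomposition."""

    def __init__(self, graph: AdjacencyGraph):
        self.graph = graph
        self.alive: dict[int, Edge] = {e.eid: e for e in graph.edges}
        self.on_a: dict[Extremity, set[int]] = {}
        self.on_b: dict[Extremity, set[int]] = {}
        for e in graph.edges:
            self.on_a.setdefault(e.a_ext, set()).add(e.eid)
            self.on_b.setdefault(e.b_ext, set()).add(e.eid)
        self.covered_a: set[int] = set()
        self.covered_b: set[int] = set()

    def remove_edge(self, edge: Edge) -> None:
        if edge.eid in self.alive:
            del self.alive[edge.eid]
            self.on_a[edge.a_ext].discard(edge.eid)
            self.on_b[edge.b_ext].discard(edge.eid)

    def alive_on_a(self, ext: Extremity) -> list[Edge]:
        return [self.alive[i] for i in sorted(self.on_a.get(ext, ()))]

    def alive_on_b(self, ext: Extremity) -> list[Edge]:
        return [self.alive[i] for i in sorted(self.on_b.get(ext, ()))]

    def commit(self, edge: Edge) -> None:
        """Remove every remaining edge incompatible with *edge*.

        Only edges incident to the extremities of the committed
        occurrence (or telomere) pair can conflict, so those are the
        only ones inspected.
        """
        if edge.is_telomeric:
            sa, sb = edge.a_ext.side, edge.b_ext.side
            for e2 in self.alive_on_a(Telomere(sa)):
                if e2.b_ext.side != sb:
                    self.remove_edge(e2)
            for e2 in self.alive_on_b(Telomere(sb)):
                if e2.a_ext.side != sa:
                    self.remove_edge(e2)
            return
        fam = edge.a_ext.family
        i, j = edge.a_ext.occurrence, edge.b_ext.occurrence
        for end in ("h", "t"):
            for e2 in self.alive_on_a(GeneExtremity(fam, i, end)):
                if e2.b_ext.occurrence != j:
                    self.remove_edge(e2)
            for e2 in self.alive_on_b(GeneExtremity(fam, j, end)):
                if e2.a_ext.occurrence != i:
                    self.remove_edge(e2)

    def cover_cycle(self, cycle: Cycle) -> None:
        """Mark the cycle's vertices covered and drop their incident edges."""
        for v in cycle.a_vertices():
            self.covered_a.add(v)
            for ext in self.graph.a_vertex_extremities(v):
                for e in self.alive_on_a(ext):
                    self.remove_edge(e)
        for v in cycle.b_vertices():
            self.covered_b.add(v)
            for ext in self.graph.b_vertex_extremities(v):
                for e in self.alive_on_b(ext):
                    self.remove_edge(e)

    def first_uncovered_a_vertex(self) -> Optional[int]:
        for v in range(len(self.graph.a_adjacencies)):
            if v not in self.covered_a:
                return v
        return None


def close_consistent_cycle(
    remaining: RemainingGraph,
    start: int,
    strategy: str = "greedy",
    rng: Optional[random.Random] = None,
) -> Cycle:
    """Close one consistent cycle through A-vertex *start*.

    Extends a path edge by edge, removing edges incompatible with every
    chosen edge, until the walk returns to the start vertex.  When the
    start vertex is telomeric the walk leaves through its gene extremity
    so that the closing step is free to pick the telomere pairing found
    by the walk (which recovers the cycle-maximizing telomere matching
    of the duplicate-free case).  Strategies: ``greedy`` prefers an edge
    that immediately closes the cycle, ``first`` takes the lowest edge
    id, ``random`` draws uniformly (seeded through *rng*).
    """
    if strategy not in STRATEGIES:
        raise GenomeError(f"unknown strategy {strategy!r}")
    graph = remaining.graph
    exts = graph.a_vertex_extremities(start)
    if isinstance(exts[0], Telomere):
        out_ext, back_ext = exts[1], exts[0]
    else:
        out_ext, back_ext = exts
    side = "A"
    vertex = start
    path: list[Edge] = []
    seen_a = {start}
    seen_b: set[int] = set()
    while True:
        cands = remaining.alive_on_a(out_ext) if side == "A" else remaining.alive_on_b(out_ext)
        if not cands:
            raise DecompositionError("cycle closing stalled: no remaining edge on an open extremity")
        closing = [e for e in cands if side == "B" and e.a_vertex == start and e.a_ext == back_ext]
        if strategy == "greedy" and closing:
            edge = closing[0]
        elif strategy == "random":
            edge = rng.choice(cands) if rng is not None else cands[0]
        else:
            edge = cands[0]
        remaining.commit(edge)
        path.append(edge)
        if side == "A":
            side, vertex = "B", edge.b_vertex
            arrival: Extremity = edge.b_ext
            if vertex in seen_b:
                raise DecompositionError("cycle walk revisited a vertex")
            seen_b.add(vertex)
            out_ext = graph.b_adjacencies[vertex].other(arrival)
        else:
            side, vertex = "A", edge.a_vertex
            arrival = edge.a_ext
            if vertex == start and arrival == back_ext:
                return Cycle(tuple(path))
            if vertex in seen_a:
                raise DecompositionError("cycle walk revisited a vertex")
            seen_a.add(vertex)
            out_ext = graph.a_adjacencies[vertex].other(arrival)


def consistent_decomposition(
    a: Genome,
    b: Genome,
    strategy: str = "greedy",
    seed: Optional[int] = None,
    partition: Optional[CommonPartition] = None,
) -> Decomposition:
    """Run the full decomposition pipeline on balanced linear genomes."""
    if not is_balanced(a, b):
        raise GenomeError("genomes must be balanced")
    if not (a.is_linear and b.is_linear):
        raise GenomeError("consistent_decomposition expects linear genomes; see dcj_approx_circular")
    graph = build_adjacency_graph(a, b)
    if partition is None:
        partition = mcsp_approx(index_free_string(a), index_free_string(b))
    c2 = preserved_adjacency_cycles(partition, graph)
    remaining = RemainingGraph(graph)
    for cyc in c2:
        for e in cyc.edges:
            remaining.commit(e)
    for cyc in c2:
        remaining.cover_cycle(cyc)
    rng = random.Random(seed) if strategy == "random" else None
    c_greater: list[Cycle] = []
    while True:
        v = remaining.first_uncovered_a_vertex()
        if v is None:
            break
        cyc = close_consistent_cycle(remaining, v, strategy, rng)
        remaining.cover_cycle(cyc)
        c_greater.append(cyc)
    decomposition = Decomposition(graph, tuple(c2) + tuple(c_greater))
    validate_decomposition(decomposition)
    return decomposition


def extract_bijection(d: Decomposition) -> dict[tuple[str, int], int]:
    """Total family-preserving matching ``(family, occ_A) -> occ_B`` of *d*."""
    validate_decomposition(d)
    return dict(d.occurrence_bijection)


@dataclass(frozen=True)
class ApproxResult:
    """Outcome of the approximation pipeline."""

    distance: int
    decomposition: Optional[Decomposition]
    bijection: dict[tuple[str, int], int]
    strategy: str
    seed: Optional[int]
    #: the genomes the decomposition refers to (differ from the inputs
    #: only for circular genomes, which are linearized at an anchor)
    linear_a: Optional[Genome] = None
    linear_b: Optional[Genome] = None

    def to_record(self) -> dict:
        rec = {
            "distance": self.distance,
            "strategy": self.strategy,
            "seed": self.seed,
        }
        if self.decomposition is not None:
            rec.update(self.decomposition.to_record())
        else:
            rec.update({"n": 0, "c2": 0, "c_greater": 0, "cycles": [], "bijection": []})
        return rec


def dcj_approx_linear(
    a: Genome,
    b: Genome,
    strategy: str = "greedy",
    seed: Optional[int] = None,
) -> ApproxResult:
    """Approximate DCJ distance of balanced linear genomes.

    Returns the distance ``n - c_D`` of the computed consistent
    decomposition (an upper bound on the exact distance) together with
    the decomposition and its occurrence bijection.
    """
    if len(a) == 0 and len(b) == 0:
        return ApproxResult(0, None, {}, strategy, seed, a, b)
    d = consistent_decomposition(a, b, strategy=strategy, seed=seed)
    return ApproxResult(d.distance, d, dict(d.occurrence_bijection), strategy, seed, a, b)


def _linearize_at(symbols: tuple[SignedSymbol, ...], pos: int) -> tuple[SignedSymbol, ...]:
    """Rotate a circular gene order so the gene at *pos* comes first, forward."""
    rot = symbols[pos:] + symbols[:pos]
    if rot[0][1] == FORWARD:
        return rot
    flipped = tuple((fam, -o) for fam, o in reversed(rot))
    # the chosen gene is now last; bring it back to the front
    return flipped[-1:] + flipped[:-1]


def dcj_approx_circular(
    a: Genome,
    b: Genome,
    strategy: str = "greedy",
    seed: Optional[int] = None,
) -> ApproxResult:
    """Approximate DCJ distance of balanced circular genomes.

    Both genomes are linearized with one occurrence of a
    minimum-multiplicity anchor family first (relabelled to a fresh
    singleton family so the anchored pair is structurally forced to
    match), the linear pipeline runs for every anchor occurrence pair,
    and the best result is kept.  Taking all anchor pairs makes the
    result invariant under rotation of either input.
    """
    if not is_balanced(a, b):
        raise GenomeError("genomes must be balanced")
    if not (a.is_circular and b.is_circular):
        raise GenomeError("dcj_approx_circular expects circular genomes")
    if len(a) == 0:
        raise GenomeError("empty circular genome")
    counts = a.family_counts()
    first_seen = {fam: idx for idx, (fam, _) in reversed(list(enumerate(a.signed_symbols())))}
    anchor = min(counts, key=lambda f: (counts[f], first_seen[f]))
    fresh = anchor + "*"
    while fresh in counts:
        fresh += "*"
    a_syms = a.signed_symbols()
    b_syms = b.signed_symbols()
    a_positions = [i for i, (fam, _) in enumerate(a_syms) if fam == anchor]
    b_positions = [i for i, (fam, _) in enumerate(b_syms) if fam == anchor]
    best: Optional[ApproxResult] = None
    for pa in a_positions:
        lin_a = _linearize_at(a_syms, pa)
        lin_a = ((fresh, FORWARD),) + lin_a[1:]
        ga = Genome.from_sequence(lin_a, name=a.name or "A")
        for pb in b_positions:
            lin_b = _linearize_at(b_syms, pb)
            lin_b = ((fresh, FORWARD),) + lin_b[1:]
            gb = Genome.from_sequence(lin_b, name=b.name or "B")
            res = dcj_approx_linear(ga, gb, strategy=strategy, seed=seed)
            if best is None or res.distance < best.distance:
                best = res
    assert best is not None
    return best
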