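"""The adjacency graph AG(A, B) and consistent cycle decompositions.

For balanced genomes *A* and *B* the adjacency graph is a bipartite
multigraph whose two vertex classes are the adjacencies of *A* and of
*B*.  An edge connects two adjacencies whenever they contain extremities
of the same family at the same end (head with head, tail with tail),
irrespective of occurrence numbers; for linear genomes each telomere of
*A* is additionally connected to each telomere of *B* (4 capping edges).

With duplicate genes, vertices can have degree larger than two and the
graph admits many cycle decompositions.  A decomposition is *consistent*
when its edges induce a well-defined matching of gene occurrences (and
telomeres) between the genomes: the head-head and tail-tail edges that
pair the same two occurrences are *siblings*, and two edges are
*compatible* unless they pair one occurrence with two different
partners.  A consistent decomposition ``D`` with ``c_D`` cycles yields
the candidate distance ``d_D = n - c_D`` where ``n`` is the number of
adjacencies per genome; the exact DCJ distance is the minimum of ``d_D``
over all consistent decompositions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

from .genome_core import (
    Adjacency,
    Extremity,
    Gene,
    GeneExtremity,
    Genome,
    GenomeError,
    Telomere,
    adjacencies,
    is_balanced,
)


class DecompositionError(GenomeError):
    """A cycle set that is not a valid consistent decomposition."""


STRAIGHT = "straight"  # telomere matching L-L / R-R
CROSSED = "crossed"  # telomere matching L-R / R-L


@dataclass(frozen=True, order=True)
class Edge:
    """One edge of AG(A, B); ``eid`` is a deterministic identifier."""

    eid: int
    a_vertex: int
    b_vertex: int
    a_ext: Extremity = field(compare=False)
    b_ext: Extremity = field(compare=False)

    @property
    def is_telomeric(self) -> bool:
        return isinstance(self.a_ext, Telomere)

    def pairing(self) -> tuple:
        """Occurrence (or telomere) pairing this edge commits to."""
        if self.is_telomeric:
            return ("tel", self.a_ext.side, self.b_ext.side)
        return (self.a_ext.family, self.a_ext.occurrence, self.b_ext.occurrence)

    def __str__(self) -> str:  # pragma: no cover
        return f"[{self.a_ext}|{self.b_ext}]"


@dataclass(frozen=True)
class Cycle:
    """A closed alternating sequence of edges of AG(A, B)."""

    edges: tuple[Edge, ...]

    @property
    def length(self) -> int:
        return len(self.edges)

    def a_vertices(self) -> set[int]:
        return {e.a_vertex for e in self.edges}

    def b_vertices(self) -> set[int]:
        return {e.b_vertex for e in self.edges}


class AdjacencyGraph:
    """AG(A, B) with deterministic edge identifiers and extremity indexes."""

    def __init__(self, a: Genome, b: Genome):
        if not is_balanced(a, b):
            raise GenomeError("adjacency graph requires balanced genomes of equal topology")
        self.a_genome = a
        self.b_genome = b
        self.a_adjacencies: tuple[Adjacency, ...] = adjacencies(a)
        self.b_adjacencies: tuple[Adjacency, ...] = adjacencies(b)
        self._a_vertex_of: dict[Extremity, int] = {}
        self._b_vertex_of: dict[Extremity, int] = {}
        for idx, adj in enumerate(self.a_adjacencies):
            for ext in adj.extremities():
                self._a_vertex_of[ext] = idx
        for idx, adj in enumerate(self.b_adjacencies):
            for ext in adj.extremities():
                self._b_vertex_of[ext] = idx

        specs: list[tuple[tuple, Extremity, Extremity]] = []
        fam_counts = a.family_counts()
        for fam in sorted(fam_counts):
            m = fam_counts[fam]
            for end in ("h", "t"):
                for i in range(1, m + 1):
                    for j in range(1, m + 1):
                        ea = GeneExtremity(fam, i, end)
                        eb = GeneExtremity(fam, j, end)
                        key = (0, self._a_vertex_of[ea], self._b_vertex_of[eb], end, fam, i, j)
                        specs.append((key, ea, eb))
        if a.is_linear:
            for sa in ("L", "R"):
                for sb in ("L", "R"):
                    ea, eb = Telomere(sa), Telomere(sb)
                    key = (1, self._a_vertex_of[ea], self._b_vertex_of[eb], "", "", 0, 0)
                    specs.append((key, ea, eb))
        specs.sort(key=lambda s: s[0])
        self.edges: tuple[Edge, ...] = tuple(
            Edge(eid, self._a_vertex_of[ea], self._b_vertex_of[eb], ea, eb)
            for eid, (_, ea, eb) in enumerate(specs)
        )
        self.edge_by_extremities: dict[tuple[Extremity, Extremity], Edge] = {
            (e.a_ext, e.b_ext): e for e in self.edges
        }
        self.a_incident: dict[Extremity, tuple[Edge, ...]] = {}
        self.b_incident: dict[Extremity, tuple[Edge, ...]] = {}
        for e in self.edges:
            self.a_incident.setdefault(e.a_ext, ())
            self.a_incident[e.a_ext] += (e,)
            self.b_incident.setdefault(e.b_ext, ())
            self.b_incident[e.b_ext] += (e,)

    @property
    def n(self) -> int:
        """Number of adjacencies per genome (the n of d = n - c)."""
        return len(self.a_adjacencies)

    @property
    def num_vertices(self) -> int:
        return len(self.a_adjacencies) + len(self.b_adjacencies)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def a_vertex_extremities(self, v: int) -> tuple[Extremity, Extremity]:
        return self.a_adjacencies[v].extremities()

    def b_vertex_extremities(self, v: int) -> tuple[Extremity, Extremity]:
        return self.b_adjacencies[v].extremities()

    def sibling(self, edge: Edge) -> Edge:
        """The edge pairing the same occurrences at the opposite end."""
        if edge.is_telomeric:
            raise GenomeError("telomere edges have no sibling")
        return self.edge_by_extremities[(edge.a_ext.other_end, edge.b_ext.other_end)]


def build_adjacency_graph(a: Genome, b: Genome) -> AdjacencyGraph:
    """Construct AG(A, B) for balanced genomes of equal topology."""
    return AdjacencyGraph(a, b)


def compatible(e: Edge, f: Edge) -> bool:
    """Whether two edges can coexist in one consistent decomposition.

    Siblings are compatible; edges pairing distinct occurrences of the
    same family are compatible; edges of distinct families always are.
    Incompatibility arises exactly when one occurrence (or telomere)
    would be paired with two different partners.
    """
    if e == f:
        return True
    if e.is_telomeric and f.is_telomeric:
        return (e.a_ext.side == f.a_ext.side) == (e.b_ext.side == f.b_ext.side)
    if e.is_telomeric or f.is_telomeric:
        return True
    if e.a_ext.family != f.a_ext.family:
        return True
    return (e.a_ext.occurrence == f.a_ext.occurrence) == (
        e.b_ext.occurrence == f.b_ext.occurrence
    )


def _pairing_maps(edges: Iterable[Edge]) -> Optional[tuple[dict, dict, dict, dict]]:
    """Partial occurrence/telomere matchings induced by an edge set, or None."""
    a_to_b: dict[tuple[str, int], int] = {}
    b_to_a: dict[tuple[str, int], int] = {}
    tel_a: dict[str, str] = {}
    tel_b: dict[str, str] = {}
    for e in set(edges):
        if e.is_telomeric:
            sa, sb = e.a_ext.side, e.b_ext.side
            if tel_a.setdefault(sa, sb) != sb or tel_b.setdefault(sb, sa) != sa:
                return None
        else:
            fam = e.a_ext.family
            i, j = e.a_ext.occurrence, e.b_ext.occurrence
            if a_to_b.setdefault((fam, i), j) != j or b_to_a.setdefault((fam, j), i) != i:
                return None
    return a_to_b, b_to_a, tel_a, tel_b


def is_consistent(cycles: Iterable[Cycle]) -> bool:
    """True iff the union of the cycles' edge sets is pairwise compatible."""
    edges = [e for c in cycles for e in c.edges]
    return _pairing_maps(edges) is not None


@dataclass(frozen=True)
class Decomposition:
    """A consistent set of vertex-disjoint cycles covering AG(A, B)."""

    graph: AdjacencyGraph
    cycles: tuple[Cycle, ...]

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def num_cycles(self) -> int:
        return len(self.cycles)

    @property
    def c2(self) -> int:
        return sum(1 for c in self.cycles if c.length == 2)

    @property
    def c_greater(self) -> int:
        return sum(1 for c in self.cycles if c.length > 2)

    @property
    def distance(self) -> int:
        return self.n - self.num_cycles

    def edges(self) -> list[Edge]:
        return [e for c in self.cycles for e in c.edges]

    @cached_property
    def occurrence_bijection(self) -> dict[tuple[str, int], int]:
        """Family-preserving matching ``(family, occ_A) -> occ_B`` read off the edges."""
        maps = _pairing_maps(self.edges())
        if maps is None:
            raise DecompositionError("decomposition edges are not compatible")
        return dict(maps[0])

    @cached_property
    def telomere_matching(self) -> dict[str, str]:
        maps = _pairing_maps(self.edges())
        if maps is None:
            raise DecompositionError("decomposition edges are not compatible")
        return dict(maps[2])

    def to_record(self) -> dict:
        """JSON-serializable summary of the decomposition."""
        return {
            "n": self.n,
            "distance": self.distance,
            "c2": self.c2,
            "c_greater": self.c_greater,
            "cycles": [
                [[e.a_vertex, e.b_vertex] for e in c.edges] for c in self.cycles
            ],
            "bijection": [
                [fam, i, j] for (fam, i), j in sorted(self.occurrence_bijection.items())
            ],
            "telomere_matching": self.telomere_matching,
        }


def validate_decomposition(d: Decomposition) -> None:
    """Raise :class:`DecompositionError` unless *d* satisfies every invariant.

    Checked: cycles are closed alternating walks visiting each of their
    vertices once; cycles are vertex-disjoint and cover the whole graph;
    every extremity is used exactly once; the edge union is compatible
    (induces a total family-preserving occurrence bijection and, for
    linear genomes, a perfect telomere matching); the edge set is
    sibling-closed.
    """
    graph = d.graph
    covered_a: set[int] = set()
    covered_b: set[int] = set()
    used_a_ext: set[Extremity] = set()
    used_b_ext: set[Extremity] = set()
    for cyc in d.cycles:
        if cyc.length < 2 or cyc.length % 2 != 0:
            raise DecompositionError(f"cycle length {cyc.length} is not a positive even number")
        a_count: dict[int, int] = {}
        b_count: dict[int, int] = {}
        for e in cyc.edges:
            a_count[e.a_vertex] = a_count.get(e.a_vertex, 0) + 1
            b_count[e.b_vertex] = b_count.get(e.b_vertex, 0) + 1
            if e.a_ext in used_a_ext or e.b_ext in used_b_ext:
                raise DecompositionError(f"extremity of edge {e} used more than once")
            used_a_ext.add(e.a_ext)
            used_b_ext.add(e.b_ext)
        if any(c != 2 for c in a_count.values()) or any(c != 2 for c in b_count.values()):
            raise DecompositionError("a cycle must touch each of its vertices exactly twice")
        # connectivity of the cycle (single closed walk, not two disjoint ones)
        comp = {next(iter(a_count)): 0}
        frontier = [("A", next(iter(a_count)))]
        reached_edges = 0
        seen_edges: set[int] = set()
        while frontier:
            side, v = frontier.pop()
            for e in cyc.edges:
                if e.eid in seen_edges:
                    continue
                if side == "A" and e.a_vertex == v:
                    seen_edges.add(e.eid)
                    frontier.append(("B", e.b_vertex))
                elif side == "B" and e.b_vertex == v:
                    seen_edges.add(e.eid)
                    frontier.append(("A", e.a_vertex))
        if len(seen_edges) != cyc.length:
            raise DecompositionError("cycle edges do not form a single closed walk")
        if covered_a & set(a_count) or covered_b & set(b_count):
            raise DecompositionError("cycles are not vertex-disjoint")
        covered_a |= set(a_count)
        covered_b |= set(b_count)
    if covered_a != set(range(len(graph.a_adjacencies))) or covered_b != set(
        range(len(graph.b_adjacencies))
    ):
        raise DecompositionError("cycles do not cover all vertices")
    edges = d.edges()
    maps = _pairing_maps(edges)
    if maps is None:
        raise DecompositionError("edge union is not compatible")
    a_to_b, b_to_a, tel_a, tel_b = maps
    fam_counts = graph.a_genome.family_counts()
    expected = {(fam, i) for fam, m in fam_counts.items() for i in range(1, m + 1)}
    if set(a_to_b) != expected or set(b_to_a) != expected:
        raise DecompositionError("occurrence matching is not a total bijection")
    if graph.a_genome.is_linear and (set(tel_a) != {"L", "R"} or set(tel_b) != {"L", "R"}):
        raise DecompositionError("telomeres are not perfectly matched")
    edge_set = set(edges)
    for e in edges:
        if not e.is_telomeric and graph.sibling(e) not in edge_set:
            raise DecompositionError(f"edge {e} present without its sibling")


def distance_of(d: Decomposition) -> int:
    """``n - c_D`` of a validated consistent decomposition."""
    validate_decomposition(d)
    return d.distance


def decomposition_from_matching(
    graph: AdjacencyGraph,
    bijection: Mapping[tuple[str, int], int],
    telomere_matching: Optional[str] = None,
) -> Decomposition:
    """The unique decomposition induced by an occurrence bijection.

    Fixing, for every family, which occurrence of *A* is matched with
    which occurrence of *B* (plus, for linear genomes, one of the two
    telomere matchings) leaves every vertex with degree two, so the
    selected edges decompose into cycles deterministically.
    """
    a_genome = graph.a_genome
    fam_counts = a_genome.family_counts()
    for fam, m in fam_counts.items():
        imgs = [bijection.get((fam, i)) for i in range(1, m + 1)]
        if sorted(imgs) != list(range(1, m + 1)):
            raise GenomeError(f"bijection is not a permutation of occurrences of family {fam!r}")
    if a_genome.is_linear:
        if telomere_matching not in (STRAIGHT, CROSSED):
            raise GenomeError("linear genomes require a telomere matching: 'straight' or 'crossed'")
        tel_map = {"L": "L", "R": "R"} if telomere_matching == STRAIGHT else {"L": "R", "R": "L"}
    else:
        tel_map = {}

    inverse = {(fam, j): i for (fam, i), j in bijection.items()}

    def image(ext: Extremity) -> Extremity:
        if isinstance(ext, Telomere):
            return Telomere(tel_map[ext.side])
        return GeneExtremity(ext.family, bijection[(ext.family, ext.occurrence)], ext.end)

    def preimage(ext: Extremity) -> Extremity:
        if isinstance(ext, Telomere):
            inv = {v: k for k, v in tel_map.items()}
            return Telomere(inv[ext.side])
        return GeneExtremity(ext.family, inverse[(ext.family, ext.occurrence)], ext.end)

    visited_a: set[int] = set()
    cycles: list[Cycle] = []
    for start in range(len(graph.a_adjacencies)):
        if start in visited_a:
            continue
        first_ext, back_ext = graph.a_vertex_extremities(start)
        edges: list[Edge] = []
        vertex, out_ext = start, first_ext
        while True:
            visited_a.add(vertex)
            b_ext = image(out_ext)
            edge = graph.edge_by_extremities[(out_ext, b_ext)]
            edges.append(edge)
            b_adj = graph.b_adjacencies[edge.b_vertex]
            b_other = b_adj.other(b_ext)
            a_ext2 = preimage(b_other)
            edge2 = graph.edge_by_extremities[(a_ext2, b_other)]
            edges.append(edge2)
            vertex = edge2.a_vertex
            if vertex == start and a_ext2 == back_ext:
                break
            a_adj = graph.a_adjacencies[vertex]
            out_ext = a_adj.other(a_ext2)
        cycles.append(Cycle(tuple(edges)))
    return Decomposition(graph, tuple(cycles))


def all_occurrence_bijections(a: Genome) -> Iterable[dict[tuple[str, int], int]]:
    """Every family-wise occurrence bijection (for brute-force enumeration)."""
    fams = sorted(a.family_counts().items())
    per_family = [
        [dict(zip(((fam, i) for i in range(1, m + 1)), perm)) for perm in itertools.permutations(range(1, m + 1))]
        for fam, m in fams
    ]
    for combo in itertools.product(*per_family):
        bij: dict[tuple[str, int], int] = {}
        for part in combo:
            bij.update(part)
        yield bij
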