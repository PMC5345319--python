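"""Signed gene-order genomes with duplicate genes.

A genome here is a single chromosome, linear or circular, written as an
ordered sequence of oriented genes.  A gene belongs to a *family* (its
symbol), has an orientation (forward or reverse) and an *occurrence*
number that distinguishes the copies of one family inside a genome.  The
two ends of an oriented gene are its *tail* (``t``) and *head* (``h``)
extremities; a linear chromosome is flanked by two telomeres.

An *adjacency* is an unordered pair of consecutive extremities (one of
which may be a telomere).  A linear genome with ``m`` genes has ``m + 1``
adjacencies, a circular one has ``m``.  The DCJ (double cut and join)
operation cuts two adjacencies and rejoins the four open ends in a new
way; on a single chromosome the "keep" rejoin is an inversion of the
segment between the cuts.

Genomes are read and written in a GRIMM-style dialect: a header line
``>name``, then whitespace-separated signed family tokens (``-`` prefix
for reverse orientation) terminated by ``$`` (linear) or ``@``
(circular).  Occurrence numbers are assigned left to right per family,
starting at 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, Union

FORWARD = 1
REVERSE = -1
LINEAR = "linear"
CIRCULAR = "circular"

#: A signed family symbol: ``(family, orientation)`` with orientation +1/-1.
SignedSymbol = tuple[str, int]


class GenomeError(ValueError):
    """Invalid genome data or an operation that cannot be applied."""


class ParseError(GenomeError):
    """Malformed genome text; the message names the offending line/column."""


@dataclass(frozen=True, order=True)
class Gene:
    """One occurrence of a gene family with an orientation."""

    family: str
    orient: int = FORWARD
    occurrence: int = 1

    def __post_init__(self) -> None:
        if self.orient not in (FORWARD, REVERSE):
            raise GenomeError(f"orientation must be +1 or -1, got {self.orient!r}")
        if self.occurrence < 1:
            raise GenomeError(f"occurrence must be >= 1, got {self.occurrence!r}")

    def reverse(self) -> "Gene":
        """The same occurrence read in the opposite direction."""
        return Gene(self.family, -self.orient, self.occurrence)

    @property
    def symbol(self) -> SignedSymbol:
        return (self.family, self.orient)

    def __str__(self) -> str:  # pragma: no cover - display helper
        sign = "" if self.orient == FORWARD else "-"
        return f"{sign}{self.family}_{self.occurrence}"


@dataclass(frozen=True, order=True)
class GeneExtremity:
    """Head (``h``) or tail (``t``) of one gene occurrence."""

    family: str
    occurrence: int
    end: str  # "h" or "t"

    def __post_init__(self) -> None:
        if self.end not in ("h", "t"):
            raise GenomeError(f"extremity end must be 'h' or 't', got {self.end!r}")

    @property
    def other_end(self) -> "GeneExtremity":
        return GeneExtremity(self.family, self.occurrence, "t" if self.end == "h" else "h")

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.family}_{self.occurrence}^{self.end}"


@dataclass(frozen=True, order=True)
class Telomere:
    """An end of a linear chromosome; ``side`` is 'L' or 'R'."""

    side: str

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise GenomeError(f"telomere side must be 'L' or 'R', got {self.side!r}")

    def __str__(self) -> str:  # pragma: no cover
        return "o"


Extremity = Union[GeneExtremity, Telomere]


def left_extremity(gene: Gene) -> GeneExtremity:
    """Extremity seen first when reading the gene left to right."""
    return GeneExtremity(gene.family, gene.occurrence, "t" if gene.orient == FORWARD else "h")


def right_extremity(gene: Gene) -> GeneExtremity:
    return GeneExtremity(gene.family, gene.occurrence, "h" if gene.orient == FORWARD else "t")


@dataclass(frozen=True)
class Adjacency:
    """Unordered pair of consecutive extremities (stored in chromosome order)."""

    first: Extremity
    second: Extremity

    def __post_init__(self) -> None:
        if isinstance(self.first, Telomere) and isinstance(self.second, Telomere):
            raise GenomeError("an adjacency may contain at most one telomere")

    def extremities(self) -> tuple[Extremity, Extremity]:
        return (self.first, self.second)

    def other(self, ext: Extremity) -> Extremity:
        if ext == self.first:
            return self.second
        if ext == self.second:
            return self.first
        raise GenomeError(f"extremity {ext} not in adjacency {self}")

    def is_telomeric(self) -> bool:
        return isinstance(self.first, Telomere) or isinstance(self.second, Telomere)

    def __str__(self) -> str:  # pragma: no cover
        return f"{{{self.first}, {self.second}}}"


@dataclass(frozen=True)
class Genome:
    """A unichromosomal genome: ordered genes plus a topology."""

    genes: tuple[Gene, ...]
    topology: str = LINEAR
    name: str = ""

    def __post_init__(self) -> None:
        if self.topology not in (LINEAR, CIRCULAR):
            raise GenomeError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        seen: dict[str, set[int]] = {}
        for g in self.genes:
            seen.setdefault(g.family, set()).add(g.occurrence)
        for fam, occs in seen.items():
            m = sum(1 for g in self.genes if g.family == fam)
            if occs != set(range(1, m + 1)):
                raise GenomeError(
                    f"occurrence numbers of family {fam!r} must be exactly 1..{m}, got {sorted(occs)}"
                )

    @classmethod
    def from_sequence(
        cls,
        symbols: Iterable[SignedSymbol],
        topology: str = LINEAR,
        name: str = "",
    ) -> "Genome":
        """Build a genome from signed symbols, numbering occurrences left to right."""
        counts: Counter[str] = Counter()
        genes = []
        for fam, orient in symbols:
            counts[fam] += 1
            genes.append(Gene(fam, orient, counts[fam]))
        return cls(tuple(genes), topology, name)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    @property
    def is_linear(self) -> bool:
        return self.topology == LINEAR

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def family_counts(self) -> dict[str, int]:
        """Multiset of gene families, family -> number of occurrences."""
        return dict(Counter(g.family for g in self.genes))

    def signed_symbols(self) -> tuple[SignedSymbol, ...]:
        return tuple(g.symbol for g in self.genes)


# ---------------------------------------------------------------------------
# GRIMM-style parsing and writing
# ---------------------------------------------------------------------------

_TERMINATORS = {"$": LINEAR, "@": CIRCULAR}


def _tokenize(text: str) -> Iterator[tuple[str, int, int]]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        col = 0
        for tok in line.split():
            col = line.index(tok, col) + 1
            yield tok, lineno, col
            col += len(tok) - 1


def parse_genomes(text: str) -> list[Genome]:
    """Parse every ``>name`` record of a GRIMM-style file (one chromosome each)."""
    genomes: list[Genome] = []
    name = ""
    symbols: list[SignedSymbol] = []
    in_record = False
    last_pos = (0, 0)
    for tok, lineno, col in _tokenize(text):
        last_pos = (lineno, col)
        if tok.startswith(">"):
            if in_record and symbols:
                raise ParseError(f"line {lineno}, col {col}: record {name!r} missing '$' or '@' terminator")
            name = tok[1:]
            symbols = []
            in_record = True
        elif tok in _TERMINATORS:
            if not symbols:
                raise ParseError(f"line {lineno}, col {col}: empty chromosome")
            genomes.append(Genome.from_sequence(symbols, _TERMINATORS[tok], name))
            symbols = []
            in_record = False
        else:
            orient = FORWARD
            if tok.startswith("-"):
                orient = REVERSE
                tok = tok[1:]
            if not tok or tok.startswith("-"):
                raise ParseError(f"line {lineno}, col {col}: malformed token")
            symbols.append((tok, orient))
    if symbols:
        lineno, col = last_pos
        raise ParseError(f"line {lineno}, col {col}: missing '$' or '@' terminator")
    return genomes


def parse_genome(text: str) -> Genome:
    """Parse a single-chromosome GRIMM-style record."""
    genomes = parse_genomes(text)
    if not genomes:
        raise ParseError("no genome record found")
    if len(genomes) > 1:
        raise ParseError(f"expected one chromosome, found {len(genomes)} records")
    return genomes[0]


def write_genome(genome: Genome) -> str:
    """GRIMM-style text for a genome; round-trips through :func:`parse_genome`."""
    toks = [("" if g.orient == FORWARD else "-") + g.family for g in genome.genes]
    terminator = "$" if genome.is_linear else "@"
    return f">{genome.name}\n{' '.join(toks + [terminator])}\n"


# ---------------------------------------------------------------------------
# Adjacencies, strings, balance
# ---------------------------------------------------------------------------

def adjacencies(genome: Genome) -> tuple[Adjacency, ...]:
    """Ordered adjacencies of a genome (telomeric ones first/last if linear)."""
    if len(genome) == 0:
        raise GenomeError("cannot list adjacencies of an empty genome")
    genes = genome.genes
    adj: list[Adjacency] = []
    if genome.is_linear:
        adj.append(Adjacency(Telomere("L"), left_extremity(genes[0])))
        for prev, nxt in zip(genes, genes[1:]):
            adj.append(Adjacency(right_extremity(prev), left_extremity(nxt)))
        adj.append(Adjacency(right_extremity(genes[-1]), Telomere("R")))
    else:
        for i, g in enumerate(genes):
            adj.append(Adjacency(right_extremity(genes[i - 1]), left_extremity(g)))
    return tuple(adj)


def index_free_string(genome: Genome) -> tuple[SignedSymbol, ...]:
    """Gene sequence with telomeres and occurrence indices stripped (linear only)."""
    if not genome.is_linear:
        raise GenomeError("index-free strings are defined for linear genomes; linearize first")
    return genome.signed_symbols()


def is_balanced(a: Genome, b: Genome) -> bool:
    """True iff both genomes have the same family multiset and topology."""
    return a.topology == b.topology and a.family_counts() == b.family_counts()


def occ(genome: Genome) -> int:
    """Maximum number of occurrences of any family (the duplication bound k)."""
    if len(genome) == 0:
        raise GenomeError("occ is undefined for an empty genome")
    return max(genome.family_counts().values())


# ---------------------------------------------------------------------------
# The DCJ operation
# ---------------------------------------------------------------------------

SWAP_KEEP = "swap-keep"
SWAP_CROSS = "swap-cross"


def apply_dcj(genome: Genome, cut1: int, cut2: int, rejoin: str = SWAP_KEEP) -> Genome:
    """Apply one DCJ: cut two adjacencies and rejoin the open ends.

    Cut positions are 0-based indices into :func:`adjacencies`.  With the
    ``swap-keep`` rejoin the result is the inversion of the segment
    between the cuts.  The ``swap-cross`` rejoin is applied literally on
    the adjacency set; if it would split the genome into more than one
    chromosome a :class:`GenomeError` is raised (this package models
    unichromosomal genomes only).
    """
    if cut1 == cut2:
        raise GenomeError("the two cut positions must be distinct")
    if rejoin not in (SWAP_KEEP, SWAP_CROSS):
        raise GenomeError(f"unknown rejoin {rejoin!r}")
    adj = adjacencies(genome)
    n = len(adj)
    for c in (cut1, cut2):
        if not 0 <= c < n:
            raise GenomeError(f"cut position {c} out of range 0..{n - 1}")
    i, j = sorted((cut1, cut2))
    u1, v1 = adj[i].extremities()
    u2, v2 = adj[j].extremities()
    if rejoin == SWAP_KEEP:
        new_pairs = [(u1, u2), (v1, v2)]
    else:
        new_pairs = [(u1, v2), (v1, u2)]
    rest = [adj[p] for p in range(n) if p not in (i, j)]
    pairs = [a.extremities() for a in rest] + new_pairs
    return _assemble(pairs, name=genome.name)


def _assemble(pairs: Sequence[tuple[Extremity, Extremity]], name: str = "") -> Genome:
    """Rebuild a unichromosomal genome from an adjacency multiset.

    Raises :class:`GenomeError` if the adjacencies do not chain into a
    single linear or circular chromosome.
    """
    partner: dict[GeneExtremity, Extremity] = {}
    tel_partner: dict[str, Extremity] = {}
    all_occurrences: set[tuple[str, int]] = set()
    tel_tel = 0
    for x, y in pairs:
        if isinstance(x, Telomere) and isinstance(y, Telomere):
            tel_tel += 1
            continue
        for a, b in ((x, y), (y, x)):
            if isinstance(a, GeneExtremity):
                if a in partner:
                    raise GenomeError(f"extremity {a} used twice")
                partner[a] = b
                all_occurrences.add((a.family, a.occurrence))
            else:
                if a.side in tel_partner:
                    raise GenomeError(f"telomere {a.side} used twice")
                tel_partner[a.side] = b

    def walk(start: Extremity, stop_at_start: bool) -> tuple[list[Gene], Extremity]:
        genes: list[Gene] = []
        current = start
        while True:
            if isinstance(current, Telomere):
                return genes, current
            fam, occ_no = current.family, current.occurrence
            orient = FORWARD if current.end == "t" else REVERSE
            genes.append(Gene(fam, orient, occ_no))
            exit_ext = current.other_end
            nxt = partner.get(exit_ext)
            if nxt is None:
                raise GenomeError("adjacency set does not chain into a chromosome")
            if stop_at_start and nxt == start:
                return genes, nxt
            current = nxt

    if tel_partner:
        if set(tel_partner) != {"L", "R"}:
            raise GenomeError("a linear chromosome needs exactly two telomeres")
        genes, terminal = walk(tel_partner["L"], stop_at_start=False)
        if not isinstance(terminal, Telomere) or terminal.side != "R":
            raise GenomeError("left telomere does not chain to the right telomere")
        topology = LINEAR
    else:
        if not all_occurrences:
            raise GenomeError("cannot assemble an empty genome")
        start = min(partner, key=lambda e: (e.family, e.occurrence, e.end))
        genes, _ = walk(start, stop_at_start=True)
        topology = CIRCULAR
    if {(g.family, g.occurrence) for g in genes} != all_occurrences:
        raise GenomeError("result is not unichromosomal")
    return Genome(tuple(genes), topology, name)
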