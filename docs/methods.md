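# Methods

## Model

A genome is a single linear or circular chromosome: an ordered sequence of
oriented genes, each belonging to a family, with copies of one family
numbered 1..m left to right (the numbering is an arbitrary labelling; all
relabelings are equivalent, and a deterministic rule is used purely for
reproducibility).  Two genomes are *balanced* when every family has the
same number of copies in both; `k = occ` denotes the largest multiplicity.

A DCJ cuts two adjacencies (unordered pairs of consecutive gene
extremities, possibly containing a telomere) and rejoins the four open
ends.  The DCJ distance of balanced genomes equals

    d(A, B) = min over consistent decompositions D of (n − c_D),

where `n` is the adjacency count per genome (`|genes| + 1` linear,
`|genes|` circular) and `c_D` the number of cycles of `D` in the adjacency
graph.  A decomposition is *consistent* when its edge set induces a
well-defined occurrence matching: the head–head and tail–tail edges pairing
the same two copies are siblings and must travel together; two edges
conflict exactly when they would match one copy (or telomere) with two
different partners.  Consistent decompositions are in bijection with
(family-wise occurrence bijections) × (telomere matchings), which is what
the exact oracle enumerates.

## The approximation pipeline

*Common partition stage.*  The index-free strings are partitioned into
paired blocks equal up to signed reversal.  The partitioner is pluggable;
the default is iterative greedy extraction of a longest common block with
leftmost-in-A, then leftmost-in-B tie-breaks (binary search over block
length; candidate blocks compared through their normalized form).  The
greedy default always returns a valid common partition and, on the random
small-string suite, never beats the exact brute-force minimum — but no
multiplicative approximation factor is asserted of it.  The `O(k)` factor
of the distance guarantee attaches to plugging in an `O(k)` MCSP
approximation; with the greedy default the pipeline's output is an upper
bound validated per instance rather than a certified factor.

*Block mapping.*  Blocks are normalized (a block or its signed reversal,
whichever is lexicographically smaller under values `v(g) ∈ [1, n]`,
`v(ḡ) = v(g) + n`, first-appearance order), gathered into buckets by
length, and each bucket is split position by position so equal strings end
up grouped; A-side and B-side entries of a group are paired in order of
first appearance.  This is linear in total symbol count.

*C2 and cycle closing.*  Each mapped block pair of length `l` yields `l−1`
preserved adjacencies, realized as 2-cycles.  Their vertices are removed
and edges incompatible with their edges pruned; the siblings of chosen
edges survive pruning and are forced into later cycles, which is what makes
the final decomposition sibling-closed (the set `C2` alone is not: siblings
of edges at block boundaries belong to the longer cycles).  The remainder
is decomposed by walking paths vertex by vertex: the walk leaves a vertex
through the extremity it did not arrive by, chooses an incident edge, and
immediately prunes edges incompatible with the choice, so the closing of a
consistent cycle is guaranteed — every unmatched copy always retains edges
to every unmatched partner copy, since the graph contains all same-family
same-end edges.

Edge choice within the walk is the `strategy` parameter:

- `greedy` (default): prefer an edge that immediately closes the current
  cycle, otherwise lowest edge id.  When the walk starts at a telomeric
  vertex it leaves through the gene extremity, so the closing step pairs
  the two telomeres the walk discovered — exactly the cycle-maximizing
  telomere matching of the duplicate-free case.  This makes the pipeline
  exact at `k = 1`, which the test-suite asserts.
- `first`: lowest edge id (fully deterministic baseline).
- `random`: seeded uniform choice, for sensitivity checks.

Edge ids are deterministic (sorted by A-vertex, B-vertex, end, occurrence
pair), so identical inputs and seeds give identical decompositions.

*Circular genomes.*  Both genomes are linearized with one occurrence of an
anchor family placed first with forward orientation; the anchored
occurrence is relabelled to a fresh singleton family so its matching is
structurally forced, and the linear pipeline runs on the rest.  The anchor
family has minimum multiplicity (ties: first appearance in A).  The design
choice here, where the design was genuinely open: the minimum is taken over
**all** anchor-occurrence pairs (A-copies × B-copies, at most k² runs)
rather than fixing one A-copy, because a fixed "first" copy depends on the
rotation in which the input happens to be written; taking all pairs makes
the result invariant under rotation of either genome, which the property
tests exercise.  Degenerate inputs: two empty genomes have distance 0 (no
decomposition object); single-gene genomes go through the general path.

## Exact oracles

- `dcj_exact_small`: minimum of `n − c` over all enumerated consistent
  decompositions.  The enumeration size `Π_g m(g)! × 2` must stay under a
  cap (default 10⁵); above it the oracle raises rather than approximate.
- `max_c2_and_constrained_min`: over the same enumeration, the maximum
  2-cycle count and the best distance among decompositions attaining it —
  the ideal outcome of a "maximize 2-cycles first" strategy, empirically a
  2-approximation on the random suite.
- `mcsp_exact_small`: exact minimum common partition size by enumerating
  split patterns by increasing block count (strings capped at length 12).
- `bfs_dcj_distance`: breadth-first search over actual DCJ operations on
  adjacency sets (multichromosomal intermediates allowed, as the DCJ model
  does), independent of the cycle formalism; restricted to ≤ 6 genes and
  used to ground the other oracles.

## Simulator

The generator reproduces the duplication-then-divergence protocol: an
identity ancestor of `s` distinct forward families receives
`floor(s / 2l)` segmental duplications of length `l` — segment start
uniform among fitting positions, copy inserted (orientation preserved) at a
uniform gap of the *growing* genome, so later duplications can copy earlier
copies — giving `1.5 s` genes and mean multiplicity 1.5 whenever `l`
divides `s/2`.  Two extant genomes then evolve independently by `r`
uniform reversals (two distinct uniform cut gaps each), so their simulated
evolutionary distance is `2r` by construction.  Ancestor positions ride
along through every operation and define the reference gene matching; the
true positive rate of a computed matching is the fraction of its pairs
descending from the same ancestor copy.

Defaults mirror the protocol's study conditions (`s = 1000`,
`l ∈ {1, 2, 5}` in the CLI experiment grid); the packaged evaluation runs
use `s = 100–200`, `r ≤ 50` and 3 replicates per cell, a problem size
chosen so a full grid completes in seconds while preserving the regime
`k ≈ 1.5`.  What the simulator does **not** emulate: gene loss or gain
(genomes stay balanced by construction), transpositions or translocations
(reversals only, though a general-DCJ variant of each step is trivial to
add at the call sites), length heterogeneity of real segmental
duplications, and any nucleotide-level signal.  Passing simulation tests
therefore says the method recovers orthology and distance under the
duplication+inversion model, not under arbitrary real-genome evolution.

## Numerical and engineering choices

- All quantities are small integers or exact rationals of integers; there
  is no floating-point tolerance anywhere in the core (TPR and ratios are
  reported as floats).
- Ties are broken deterministically throughout (leftmost block, lowest edge
  id, first bucket appearance), so every public function is reproducible
  given its seed.
- Validators are run, not trusted: the approximation validates its own
  decomposition (cover, disjointness, compatibility, sibling closure,
  total family-preserving bijection) before returning.
- Oracles refuse oversized instances with an explicit error instead of
  degrading silently.
- The greedy longest-common-block search is near-linear per extraction
  (binary search over lengths with dictionary lookups) rather than strictly
  linear; suffix automata over integer alphabets would restore the
  asymptotic bound but are out of proportion for the instance sizes this
  package targets.

## Known limitations

- Multichromosomal genomes and unbalanced gene content (insertions or
  deletions) are out of scope; inputs must be single chromosomes with equal
  family multisets.
- The greedy partitioner carries no proven approximation factor; the
  certified `O(k)` statement requires an MCSP approximation with that
  factor as the plug-in stage.
- The exact oracles are combinatorial by design and unusable beyond a few
  genes with multiplicity ≥ 3.
- No explicit DCJ scenario (sequence of operations) is emitted, only the
  distance, the decomposition and the gene matching.
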