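# dcjdup

DCJ rearrangement distance between **balanced unichromosomal genomes with
duplicate genes**: a fast consistent-decomposition approximation, exact
brute-force oracles for small instances, and a segmental-duplication +
reversal simulator with ortholog-recovery scoring.

Genome rearrangements — inversions, translocations, fusions, fissions — are
modelled by the double cut and join (DCJ) operation, which cuts a genome at
two positions and rejoins the four open ends differently.  For two genomes
with the same number of copies of every gene family ("balanced" genomes),
the DCJ distance is the minimum number of DCJs transforming one into the
other.  Without duplicates it is computable in linear time as `d = n − c`
(adjacencies minus cycles of the adjacency graph); with duplicates the
cycle decomposition must also choose which copy matches which, and the
problem is NP-hard.  This package is aimed at comparative-genomics work
where duplicated gene content makes the exact problem intractable but a
certified upper bound and a concrete gene matching are still wanted.

## The method

For balanced genomes *A*, *B* with `n` adjacencies each and duplication
bound `k = occ` (maximum copies of any family):

1. Build the adjacency graph AG(A, B): bipartite, adjacencies of *A* vs
   adjacencies of *B*, one edge per pair of equal gene extremities (head
   with head, tail with tail) irrespective of copy numbers, plus 4
   telomere-capping edges for linear genomes.
2. Compute a common partition of the index-free strings Â, B̂ (blocks
   matched up to signed reversal).  Every mapped block of length `l`
   contributes its `l − 1` preserved adjacencies as length-2 cycles — the
   set `C2`.  Block mapping uses normalization, bucketing by length and a
   radix-style bucket-splitting pass.
3. Remove the vertices covered by `C2` and all edges incompatible with its
   edges (two edges are incompatible when they would match one gene copy
   with two different partners).
4. Greedily close consistent cycles in the remainder, pruning incompatible
   edges after every chosen edge, giving `C_>`.
5. Return `D = C2 ∪ C_>` and the distance `d_D = n − c_D`, together with the
   occurrence bijection (gene matching) that `D` induces.

`d_D` is always an upper bound on the exact distance, is exact for
duplicate-free inputs, and carries an `O(k)` approximation guarantee when
the partition stage is an `O(k)` MCSP approximation.  Circular genomes are
handled by anchored linearization.  The exact oracle enumerates all
consistent decompositions (family-wise occurrence bijections × telomere
matchings) on small instances, and an independent breadth-first search over
actual DCJ operations cross-checks it on tiny ones.

## Worked example

```python
from dcjdup import parse_genome, dcj_exact_small, dcj_approx_linear, max_c2_and_constrained_min

A = parse_genome(">A\n-c a f -e d -a b i -h g -b $")
B = parse_genome(">B\nc a d e f -a b g h i -b $")
print(dcj_exact_small(A, B)[0])           # 6
print(max_c2_and_constrained_min(A, B))   # (2, 7)
print(dcj_approx_linear(A, B).distance)   # 7
```

Or run `python examples/worked_pair_distance.py`:

```
genes per genome:       11
adjacencies (n):        12
exact DCJ distance:     6   (n - c = 12 - 6)
max 2-cycles first:     c2 = 2, best distance 7
approximation:          7   (c2 = 2, longer cycles = 3)
```

The two genomes are 6 DCJs apart; at most 2 preserved adjacencies can be
kept as 2-cycles in any consistent decomposition, and the best
decomposition doing so has distance 7 — so greedily keeping 2-cycles is
good (here within factor 7/6) but not optimal.  The other examples show the
common-partition stage (`examples/common_partition.py`) and a full
simulation study with true-positive-rate scoring of the inferred gene
matching (`examples/simulate_and_evaluate.py`).

A thin CLI wraps the same calls:

```sh
dcjdup distance A.grimm B.grimm --json   # approximation + matching
dcjdup exact A.grimm B.grimm             # brute force, small inputs only
dcjdup simulate --s 100 --l 2 --r 20 --seed 7 -o sim
dcjdup evaluate sim_A.grimm sim_B.grimm sim_ancestry.json
dcjdup experiment --s 100 --l 1 --l 2 --r 10 --r 25 -o table.tsv
```

Genome files are GRIMM-style: `>name`, signed whitespace-separated tokens,
terminated `$` (linear) or `@` (circular).

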