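"""Benchmark-instance simulation: segmental duplications plus DCJs.

An ancestor genome starts as the identity order of ``s`` distinct
forward-oriented families and undergoes ``floor(s / 2l)`` segmental
duplications of length ``l``: each duplication copies a uniformly
chosen contiguous segment (orientation preserved) and inserts the copy
at a uniformly chosen gap of the current genome, so the ancestor ends
with ``s + floor(s/2l) * l`` genes — ``1.5 s`` (mean occurrences per
family 1.5) whenever ``l`` divides ``s/2``.  Two extant genomes then
evolve independently from the ancestor through ``r`` random reversals
(the DCJs of the protocol), making their simulated evolutionary
distance ``2 r`` by construction.

Every gene copy carries its ancestor position through all operations,
which defines the *reference bijection* between the extant genomes and
with it the true positive rate of any computed occurrence matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_core import FORWARD, Genome, GenomeError, SignedSymbol
from .decomposition import dcj_approx_linear

#: one simulated gene: (family, orientation, ancestor position)
_TrackedGene = tuple[str, int, int]


@dataclass(frozen=True)
class SimulationResult:
    """Ancestor, two extant genomes, and their ancestry labelling."""

    ancestor: Genome
    extant_a: Genome
    extant_b: Genome
    #: ancestor position of each occurrence label, e.g. ("7", 2) -> 13
    ancestry_a: dict[tuple[str, int], int]
    ancestry_b: dict[tuple[str, int], int]
    s: int
    l: int
    r: int
    seed: Optional[int]

    @property
    def reference_bijection(self) -> dict[tuple[str, int], int]:
        """Occurrence matching of the extant genomes through the ancestor."""
        by_ancestor = {aid: occ for (fam, occ), aid in self.ancestry_b.items()}
        return {
            key: by_ancestor[aid] for key, aid in sorted(self.ancestry_a.items())
        }


def _tracked_to_genome(genes: Sequence[_TrackedGene], name: str) -> tuple[Genome, dict]:
    genome = Genome.from_sequence([(fam, orient) for fam, orient, _ in genes], name=name)
    ancestry = {
        (g.family, g.occurrence): aid for g, (_, _, aid) in zip(genome.genes, genes)
    }
    return genome, ancestry


def simulate_ancestor(
    s: int,
    l: int,
    rng: np.random.Generator,
    return_events: bool = False,
):
    """Ancestor gene list after ``floor(s / 2l)`` segmental duplications.

    Duplications act on the growing genome, so later events may copy
    earlier copies; segment starts are uniform among positions where
    the segment fits, insertion gaps uniform among all gaps.
    """
    if l < 1 or s < 2 * l:
        raise GenomeError(f"need s >= 2*l and l >= 1, got s={s}, l={l}")
    genes: list[tuple[str, int]] = [(str(i + 1), FORWARD) for i in range(s)]
    events = []
    for _ in range(s // (2 * l)):
        start = int(rng.integers(0, len(genes) - l + 1))
        segment = genes[start : start + l]
        gap = int(rng.integers(0, len(genes) + 1))
        genes = genes[:gap] + segment + genes[gap:]
        events.append((start, gap))
    tracked = [(fam, orient, pos) for pos, (fam, orient) in enumerate(genes)]
    if return_events:
        return tracked, events
    return tracked


def _reversal(genes: list[_TrackedGene], i: int, j: int) -> list[_TrackedGene]:
    """Invert the segment between gaps i < j (signs flip, ancestry rides along)."""
    return genes[:i] + [(fam, -o, aid) for fam, o, aid in reversed(genes[i:j])] + genes[j:]


def simulate_extant(
    ancestor: Sequence[_TrackedGene], r: int, rng: np.random.Generator
) -> list[_TrackedGene]:
    """Apply *r* uniform reversals (two distinct uniform cut gaps each)."""
    if r < 0:
        raise GenomeError("r must be >= 0")
    genes = list(ancestor)
    gaps = len(genes) + 1
    for _ in range(r):
        i, j = sorted(int(x) for x in rng.choice(gaps, size=2, replace=False))
        genes = _reversal(genes, i, j)
    return genes


def simulate_pair(
    s: int, l: int, r: int, seed: Optional[int] = None
) -> SimulationResult:
    """Full protocol: ancestor with duplications, two extant genomes, ancestry."""
    rng = np.random.default_rng(seed)
    ancestor_tracked = simulate_ancestor(s, l, rng)
    extant_a = simulate_extant(ancestor_tracked, r, rng)
    extant_b = simulate_extant(ancestor_tracked, r, rng)
    ancestor_genome, _ = _tracked_to_genome(ancestor_tracked, "ancestor")
    genome_a, anc_a = _tracked_to_genome(extant_a, "A")
    genome_b, anc_b = _tracked_to_genome(extant_b, "B")
    return SimulationResult(
        ancestor_genome, genome_a, genome_b, anc_a, anc_b, s, l, r, seed
    )


def true_positive_rate(
    bijection: Mapping[tuple[str, int], int], result: SimulationResult
) -> float:
    """Fraction of matched occurrence pairs descending from the same ancestor copy."""
    if set(bijection) != set(result.ancestry_a):
        raise GenomeError("bijection must be total over the occurrences of extant A")
    total = len(result.ancestry_a)
    hits = sum(
        1
        for (fam, i), j in bijection.items()
        if result.ancestry_a[(fam, i)] == result.ancestry_b[(fam, j)]
    )
    return hits / total


def random_balanced_pair(
    rng: np.random.Generator,
    max_genes: int = 8,
    max_occ: int = 3,
    min_genes: int = 2,
) -> tuple[Genome, Genome]:
    """A random pair of balanced linear genomes (shared content, random orders/signs).

    Used by the small-instance evaluation suites: the gene count is
    uniform in ``[min_genes, max_genes]`` and family multiplicities are
    capped at ``max_occ``.
    """
    m = int(rng.integers(min_genes, max_genes + 1))
    families: list[str] = []
    fam_idx = 0
    while len(families) < m:
        count = int(rng.integers(1, min(max_occ, m - len(families)) + 1))
        families.extend([chr(ord("a") + fam_idx)] * count)
        fam_idx += 1

    def scramble(name: str) -> Genome:
        order = rng.permutation(len(families))
        symbols = [
            (families[i], FORWARD if rng.integers(0, 2) == 0 else -FORWARD)
            for i in order
        ]
        return Genome.from_sequence(symbols, name=name)

    return scramble("A"), scramble("B")


def run_experiment(
    s_values: Sequence[int],
    l_values: Sequence[int],
    r_values: Sequence[int],
    replicates: int = 3,
    seed: Optional[int] = None,
    strategy: str = "greedy",
) -> pd.DataFrame:
    """Grid evaluation of the approximation against simulated truth.

    For every (s, l, r) cell and replicate: simulate a pair, run the
    approximation, record the computed distance, its difference to the
    simulated evolutionary distance ``2 r``, and the true positive rate
    of the computed occurrence matching.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in s_values:
        for l in l_values:
            for r in r_values:
                for rep in range(replicates):
                    pair_seed = int(rng.integers(0, 2**31 - 1))
                    sim = simulate_pair(s, l, r, seed=pair_seed)
                    res = dcj_approx_linear(sim.extant_a, sim.extant_b, strategy=strategy)
                    tpr = true_positive_rate(res.bijection, sim)
                    rows.append(
                        {
                            "s": s,
                            "l": l,
                            "r": r,
                            "replicate": rep,
                            "pair_seed": pair_seed,
                            "n_genes": len(sim.extant_a),
                            "distance": res.distance,
                            "simulated_distance": 2 * r,
                            "diff": res.distance - 2 * r,
                            "tpr": tpr,
                        }
                    )
    return pd.DataFrame(rows)


def plot_experiment(table: pd.DataFrame, path: str) -> None:
    """Mean (distance - 2r) and TPR against r, one line per l (optional helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for l, sub in table.groupby("l"):
        mean = sub.groupby("r")[["diff", "tpr"]].mean()
        axes[0].plot(mean.index, mean["diff"], marker="o", label=f"l={l}")
        axes[1].plot(mean.index, mean["tpr"], marker="o", label=f"l={l}")
    axes[0].set_xlabel("r")
    axes[0].set_ylabel("computed distance - 2r")
    axes[1].set_xlabel("r")
    axes[1].set_ylabel("true positive rate")
    for ax in axes:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
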