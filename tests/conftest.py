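"""Shared fixtures: the printed worked genome pairs and small helpers."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dcjdup as d

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


FIG_DUP_A = ">A\n-c a f -e d -a b i -h g -b $"
FIG_DUP_B = ">B\nc a d e f -a b g h i -b $"


def signed(text: str) -> tuple:
    """Signed string from space-separated tokens; trailing '-' = reverse."""
    out = []
    for tok in text.split():
        if tok.endswith("-"):
            out.append((tok[:-1], -1))
        else:
            out.append((tok, 1))
    return tuple(out)


@pytest.fixture(scope="session")
def worked_pair():
    """The fully printed 11-gene pair with duplicated families a and b."""
    return d.parse_genome(FIG_DUP_A), d.parse_genome(FIG_DUP_B)


@pytest.fixture(scope="session")
def inconsistency_pair():
    """The 7-gene pair (a x5, b x2) used to illustrate inconsistent cycles."""
    a = d.parse_genome(">A\na b a b a a a $")
    b = d.parse_genome(">B\nb -a b a a a a $")
    return a, b


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pairs(seed, count, max_genes=8, max_occ=3):
    gen = np.random.default_rng(seed)
    return [d.random_balanced_pair(gen, max_genes=max_genes, max_occ=max_occ) for _ in range(count)]
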