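import math

import numpy as np
import pytest

from topeseq.design import design_library
from topeseq.simulate import make_toy_genome, make_toy_proteome


def pure_levenshtein(a: str, b: str) -> int:
    """Independent O(nm) dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def binom_sf_enumerated(s: int, m: int, q: float) -> float:
    """P(X >= s) for X ~ Binomial(m, q) by full pmf summation (oracle)."""
    return sum(math.comb(m, x) * q ** x * (1 - q) ** (m - x)
               for x in range(s, m + 1))


@pytest.fixture(scope="session")
def toy_proteome():
    return make_toy_proteome(12, (70, 200), seed=42)


@pytest.fixture(scope="session")
def toy_designs(toy_proteome):
    designs, report = design_library(toy_proteome, seed=7)
    return designs, report


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(n_contigs=2, segments_per_contig=2,
                           codons_per_segment=30, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
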