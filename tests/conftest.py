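"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from growthqtl import simulate as sim

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# explicit-meiosis oracle (independent of the package's Markov-chain RIL
# simulator): gametes recombine between adjacent loci with the meiotic
# fraction r, individuals self for `generations` rounds from the F1
# ---------------------------------------------------------------------------

def meiosis_ril(r_between: np.ndarray, n_lines: int, generations: int = 10,
                seed: int = 0) -> np.ndarray:
    """Simulate selfed RILs by explicit meiosis.

    ``r_between`` holds the meiotic recombination fractions between the
    m loci (length m-1).  Returns an (n_lines, m) array of genotype codes
    0/1/2 (count of parent-B alleles) after ``generations`` selfing
    rounds starting from a fully heterozygous F1.
    """
    rng = np.random.default_rng(seed)
    m = len(r_between) + 1
    # haplotypes: 0 = parent A allele, 1 = parent B allele
    h1 = np.zeros((n_lines, m), dtype=np.int8)
    h2 = np.ones((n_lines, m), dtype=np.int8)

    def gamete(h1, h2):
        start = rng.integers(0, 2, size=n_lines)
        cross = rng.random((n_lines, m - 1)) < r_between
        strand = np.empty((n_lines, m), dtype=np.int8)
        strand[:, 0] = start
        strand[:, 1:] = (start[:, None] + np.cumsum(cross, axis=1)) % 2
        return np.where(strand == 0, h1, h2)

    for _ in range(generations):
        g1 = gamete(h1, h2)
        g2 = gamete(h1, h2)
        h1, h2 = g1, g2
    return (h1 + h2).astype(np.int8)


@pytest.fixture(scope="session")
def small_ril():
    """237 RILs on one 100 cM chromosome with 21 markers (5 cM spacing)."""
    ms = sim.MapSpec([("1", 100.0, 21)])
    geno, mmap, bkp = sim.simulate_ril_population(ms, 237, het_rate=0.0, seed=11)
    return geno, mmap, bkp


@pytest.fixture(scope="session")
def two_chrom_ril():
    """200 RILs on two 100 cM chromosomes (11 markers each)."""
    ms = sim.MapSpec([("1", 100.0, 11), ("2", 100.0, 11)])
    geno, mmap, bkp = sim.simulate_ril_population(ms, 200, het_rate=0.0, seed=12)
    return geno, mmap, bkp


def marker_score(calls: pd.Series | np.ndarray) -> np.ndarray:
    """-1/+1 additive coding of homozygous calls (0 for het/missing)."""
    c = np.asarray(calls)
    return np.where(c == 2, 1.0, np.where(c == 0, -1.0, 0.0))
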