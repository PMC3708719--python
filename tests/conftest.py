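"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take the dumbest correct route (per-trio
enumeration, all-pairs scans, direct Monte Carlo) so they stay independent
of the vectorised implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from triorank.simulate import MISSING, TrioCohort


def oracle_trio_tallies(f: int, m: int, c: int):
    """Enumerate parental transmissions for one trio; the TDT counting oracle.

    Genotypes are allele-1 copy counts (-1 missing).  Returns the tally
    (a, b, c, d) contributed by the trio, or None when the trio is excluded
    (a missing member or no Mendelian-consistent transmission pattern).
    The doubly-heterozygous het-child trio admits two patterns, both of
    which tally one b and one c.
    """
    if MISSING in (f, m, c):
        return None
    valid = []
    for x in (0, 1):  # allele-1 copies transmitted by the father
        if (x == 1 and f == 0) or (x == 0 and f == 2):
            continue
        for y in (0, 1):
            if (y == 1 and m == 0) or (y == 0 and m == 2):
                continue
            if x + y == c:
                valid.append((x, y))
    if not valid:
        return None
    if len(valid) == 2:
        return (0, 1, 1, 0)
    ((x, y),) = valid
    tally = [0, 0, 0, 0]  # a, b, c, d
    for g, t in ((f, x), (m, y)):
        if g == 2:
            tally[0] += 1
        elif g == 1 and t == 1:
            tally[1] += 1
        elif g == 1 and t == 0:
            tally[2] += 1
        else:
            tally[3] += 1
    return tuple(tally)


def oracle_count_snp(father: np.ndarray, mother: np.ndarray,
                     child: np.ndarray) -> tuple[int, int, int, int, int]:
    """Recount one SNP's transmission table trio by trio via the oracle."""
    a = b = c = d = q = 0
    for f, m, k in zip(father, mother, child):
        t = oracle_trio_tallies(int(f), int(m), int(k))
        if t is None:
            continue
        a, b, c, d, q = a + t[0], b + t[1], c + t[2], d + t[3], q + 1
    return a, b, c, d, q


def make_cohort(father, mother, child, positions=None, chrom=1,
                population="pop") -> TrioCohort:
    """Cohort from explicit genotype matrices (trios x snps)."""
    father = np.atleast_2d(np.asarray(father, dtype=np.int8))
    mother = np.atleast_2d(np.asarray(mother, dtype=np.int8))
    child = np.atleast_2d(np.asarray(child, dtype=np.int8))
    n_snps = father.shape[1]
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 1000
    markers = pd.DataFrame({
        "snp": [f"s{i}" for i in range(n_snps)],
        "chrom": chrom, "pos": positions, "a1": "A", "a2": "B"})
    return TrioCohort(markers=markers, father=father, mother=mother,
                      child=child, population=population)


@pytest.fixture(scope="session")
def small_study():
    """A compact three-population study with planted signal, reused across
    read-only tests."""
    from triorank.pipeline import simulate_study

    return simulate_study({
        "n_snps": 3000,
        "populations": [
            {"name": "EA", "fst_param": 0.05, "n_trios": 150},
            {"name": "AA", "fst_param": 0.15, "n_trios": 60},
            {"name": "HA", "fst_param": 0.10, "n_trios": 50},
        ],
        "n_genes": 300, "n_gene_sets": 50, "missing_rate": 0.01,
    }, seed=11)


@pytest.fixture(scope="session")
def null_tdt_table():
    """TDT results for a signal-free cohort (tau = 0.5 everywhere)."""
    from triorank.association import tdt_table
    from triorank.simulate import simulate_ancestral_frequencies, simulate_trios

    freqs = simulate_ancestral_frequencies(2000, 0.1, 0.5, seed=5)
    cohort = simulate_trios(freqs, 300, seed=6)
    return tdt_table(cohort)
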