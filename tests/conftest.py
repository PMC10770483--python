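"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phla_audit.frequencies import FrequencyTable
from phla_audit.nomenclature import allele_locus


def brute_force_hit_pmf(
    pairs: list[tuple[str, str]],
    frequencies_by_locus: dict[str, dict[str, float]],
) -> dict[int, float]:
    """Exact hit pmf by full enumeration of ordered genotypes across loci.

    Independent oracle: enumerates every ordered genotype (a1, a2) per locus
    with probability f1*f2 (which realizes HWE: f^2 on the diagonal, 2*f1*f2
    off it once both orders are summed) and counts, per dataset pair, whether
    its allele appears in the genotype — once, regardless of zygosity.
    """
    per_locus = []
    loci = list(frequencies_by_locus)
    for locus in loci:
        items = list(frequencies_by_locus[locus].items())
        per_locus.append(
            [((a1, a2), f1 * f2) for a1, f1 in items for a2, f2 in items]
        )
    pmf: dict[int, float] = {}
    for combo in itertools.product(*per_locus):
        prob = math.prod(p for _, p in combo)
        hits = 0
        for locus, (genotype, _) in zip(loci, combo):
            hits += sum(
                1
                for _, allele in pairs
                if allele_locus(allele) == locus and allele in genotype
            )
        pmf[hits] = pmf.get(hits, 0.0) + prob
    return pmf


def random_coverage_instance(rng: np.random.Generator, max_loci: int = 2):
    """A random small coverage instance: <=2 loci, <=3 alleles per locus.

    Returns (pairs, frequencies_by_locus). Pairs may reference alleles absent
    from the frequency map (frequency 0) to exercise that path.
    """
    loci = ["A", "B"][: int(rng.integers(1, max_loci + 1))]
    freqs_by_locus = {}
    allele_pool = []
    for locus in loci:
        k = int(rng.integers(1, 4))
        f = rng.dirichlet(np.full(k, 0.8))
        alleles = [f"{locus}*{i + 1:02d}:01" for i in range(k)]
        freqs_by_locus[locus] = dict(zip(alleles, f.tolist()))
        allele_pool.extend(alleles)
        if rng.random() < 0.3:  # dataset allele unknown to this population
            allele_pool.append(f"{locus}*99:01")
    n_pairs = int(rng.integers(1, 5))
    pairs = [
        (f"PEPTIDE{i}", str(rng.choice(allele_pool))) for i in range(n_pairs)
    ]
    return pairs, freqs_by_locus


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def small_frequency_frame() -> pd.DataFrame:
    """Two populations, loci A and B complete for one, A only for the other."""
    rows = [
        ("Popland General", "Popland", "A", "A*01:01", 0.6, 100),
        ("Popland General", "Popland", "A", "A*02:01", 0.4, 100),
        ("Popland General", "Popland", "B", "B*07:02", 1.0, 100),
        ("Otherland General", "Otherland", "A", "A*01:01", 1.0, 50),
    ]
    return pd.DataFrame(
        rows,
        columns=["population", "country", "locus", "allele", "frequency", "sample_size"],
    )


@pytest.fixture
def small_frequency_table(small_frequency_frame) -> FrequencyTable:
    return FrequencyTable(small_frequency_frame)
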