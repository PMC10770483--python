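"""Population coverage of a pHLA dataset under Hardy-Weinberg sampling.

Given the unique (peptide, allele) pairs of a dataset and a population's
allele frequencies, a random individual of that population carries two
alleles per locus with Hardy-Weinberg genotype probabilities (f_i^2 for a
homozygote, 2 f_i f_j otherwise), independently across loci. Each dataset
pair is "hit" when the individual carries its allele. The distribution of
the per-individual hit count yields:

* coverage   — P(at least one hit) = 1 - pmf(0);
* PC90       — the largest n with P(hits >= n) >= 0.90, i.e. the number of
               dataset points guaranteed to 90% of the population;
* sPC90      — PC90 divided by the dataset size, comparable across datasets.

This is the coverage construction of Bui et al. as implemented in the IEDB
population-coverage tool, repurposed to score dataset representativeness
rather than vaccine quality.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .nomenclature import CLASS_I_LOCI, allele_locus

_PMF_ATOL = 1e-9


class HitDistribution:
    """Probability mass function over per-individual dataset hit counts."""

    def __init__(self, pmf: np.ndarray):
        pmf = np.asarray(pmf, dtype=float)
        if pmf.ndim != 1 or pmf.size == 0:
            raise ValueError("pmf must be a nonempty 1-D array")
        if np.any(pmf < -_PMF_ATOL):
            raise ValueError("pmf has negative probabilities")
        if abs(pmf.sum() - 1.0) > _PMF_ATOL:
            raise ValueError(f"pmf sums to {pmf.sum()!r}, not 1")
        self.pmf = np.clip(pmf, 0.0, None)

    def __repr__(self) -> str:
        return f"HitDistribution(support=0..{len(self.pmf) - 1})"

    def probability(self, hits: int) -> float:
        return float(self.pmf[hits]) if 0 <= hits < len(self.pmf) else 0.0

    def tail(self, n: int) -> float:
        """P(hits >= n)."""
        if n <= 0:
            return 1.0
        return float(self.pmf[n:].sum())

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.pmf)) @ self.pmf)

    @property
    def coverage(self) -> float:
        """Probability that an individual hits at least one dataset pair."""
        return float(1.0 - self.pmf[0])

    def as_dict(self) -> dict[int, float]:
        return {h: float(p) for h, p in enumerate(self.pmf) if p > 0}


def locus_hit_distribution(
    pair_alleles: list[str],
    frequencies: dict[str, float],
    sum_tolerance: float = 1e-6,
) -> HitDistribution:
    """Exact hit pmf for one locus.

    ``pair_alleles`` are the alleles (one per dataset pair) restricted to this
    locus; ``frequencies`` is the population's allele -> frequency map for the
    locus, which must sum to 1 within ``sum_tolerance`` (include any OTHER
    residual). Dataset alleles absent from the map have frequency 0 and can
    never be hit.

    A genotype (a_i, a_j) hits every pair whose allele is a_i or a_j, each
    pair counted once — a homozygote (a, a) hits a pair for ``a`` once.
    """
    freqs = np.array(list(frequencies.values()), dtype=float)
    if freqs.size == 0 or abs(freqs.sum() - 1.0) > sum_tolerance:
        raise ValueError(
            f"locus frequencies sum to {freqs.sum() if freqs.size else 0.0}, not 1"
        )
    pair_counts = Counter(pair_alleles)
    hits = np.array([pair_counts.get(a, 0) for a in frequencies], dtype=int)

    n_max = int(pair_counts.total())
    # Group alleles by hit count: q[h] = total frequency of alleles hitting h pairs.
    q = np.zeros(n_max + 1)
    np.add.at(q, hits, freqs)
    # Two independent draws give hits c_i + c_j; correct homozygotes, whose
    # hit count is c_i (not 2 c_i), allele by allele.
    pmf = np.zeros(2 * n_max + 1)
    pmf[: 2 * len(q) - 1] = np.convolve(q, q)
    f_sq = freqs**2
    np.add.at(pmf, 2 * hits, -f_sq)
    np.add.at(pmf, hits, f_sq)
    # pairs of distinct alleles are disjoint, so hits never exceed n_max
    return HitDistribution(pmf[: n_max + 1])


def combine_loci(distributions: list[HitDistribution]) -> HitDistribution:
    """Convolve per-locus hit pmfs (loci are assumed independent)."""
    if not distributions:
        raise ValueError("need at least one per-locus distribution")
    pmf = distributions[0].pmf
    for dist in distributions[1:]:
        pmf = np.convolve(pmf, dist.pmf)
    return HitDistribution(pmf)


def pc90(dist: HitDistribution, q: float = 0.90, interpolate: bool = False) -> float:
    """Hit count guaranteed to a fraction ``q`` of the population.

    Integer mode (default): the largest n >= 0 with P(hits >= n) >= q.
    Interpolated mode: linear interpolation of the tail function between the
    bracketing integers, giving a fractional answer.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    tails = np.concatenate([[1.0], 1.0 - np.cumsum(dist.pmf)])  # tails[n] = P(hits >= n)
    tails = np.clip(tails, 0.0, 1.0)
    n = int(np.max(np.nonzero(tails >= q)))
    if not interpolate:
        return float(n)
    if n + 1 >= len(tails) or tails[n] == tails[n + 1]:
        return float(n)
    return float(n + (tails[n] - q) / (tails[n] - tails[n + 1]))


def scaled_pc90(pc90_value: float, dataset_size: int) -> float:
    """sPC90 = PC90 / dataset size, in [0, 1]."""
    if dataset_size < 1:
        raise ValueError("dataset size must be >= 1")
    return float(pc90_value) / dataset_size


@dataclass(frozen=True)
class CoverageResult:
    """Coverage statistics of one dataset for one geographic population."""

    population: str
    country: str
    income_level: str
    coverage: float
    pc90: float
    spc90: float
    dataset_size: int


def hit_distribution(
    pairs: list[tuple[str, str]],
    frequencies_by_locus: dict[str, dict[str, float]],
    loci: tuple[str, ...] = CLASS_I_LOCI,
) -> HitDistribution:
    """Exact hit pmf of a dataset across loci for one population.

    ``pairs`` are unique (peptide, allele) pairs with canonical alleles;
    ``frequencies_by_locus`` maps each locus to its allele -> frequency map.
    Loci are combined in the fixed order given by ``loci``.
    """
    if not pairs:
        raise ValueError("coverage needs at least one (peptide, allele) pair")
    per_locus = []
    for locus in loci:
        alleles = [a for _, a in pairs if allele_locus(a) == locus]
        freqs = frequencies_by_locus.get(locus, {})
        if not freqs:
            continue
        per_locus.append(locus_hit_distribution(alleles, freqs))
    if not per_locus:
        raise ValueError("no locus has both frequencies and dataset pairs")
    return combine_loci(per_locus)


def population_coverage(
    pairs: list[tuple[str, str]],
    frequencies_by_locus: dict[str, dict[str, float]],
    population: str = "",
    country: str = "",
    income_level: str = "",
    q: float = 0.90,
    interpolate: bool = False,
    loci: tuple[str, ...] = CLASS_I_LOCI,
) -> CoverageResult:
    """Coverage, PC90 and sPC90 of a dataset for one population."""
    dist = hit_distribution(pairs, frequencies_by_locus, loci)
    n = len(pairs)
    pc = pc90(dist, q=q, interpolate=interpolate)
    return CoverageResult(
        population=population,
        country=country,
        income_level=income_level,
        coverage=dist.coverage,
        pc90=pc,
        spc90=scaled_pc90(pc, n),
        dataset_size=n,
    )


def monte_carlo_hits(
    pairs: list[tuple[str, str]],
    frequencies_by_locus: dict[str, dict[str, float]],
    n_samples: int,
    seed: int,
    loci: tuple[str, ...] = CLASS_I_LOCI,
) -> HitDistribution:
    """Empirical hit pmf from simulated HWE genotypes (validation oracle).

    Samples two alleles per locus per individual from the population
    frequencies, counts dataset hits with the same once-per-pair rule as the
    exact computation, and tabulates the empirical distribution.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not pairs:
        raise ValueError("coverage needs at least one (peptide, allele) pair")
    rng = np.random.default_rng(seed)
    total_hits = np.zeros(n_samples, dtype=int)
    n_max = 0
    for locus in loci:
        freqs = frequencies_by_locus.get(locus, {})
        if not freqs:
            continue
        alleles = [a for _, a in pairs if allele_locus(a) == locus]
        counts = Counter(alleles)
        c = np.array([counts.get(a, 0) for a in freqs], dtype=int)
        p = np.array(list(freqs.values()), dtype=float)
        p = p / p.sum()
        draws = rng.choice(len(p), size=(n_samples, 2), p=p)
        hits = c[draws[:, 0]] + np.where(draws[:, 1] != draws[:, 0], c[draws[:, 1]], 0)
        total_hits += hits
        n_max += len(alleles)
    pmf = np.bincount(total_hits, minlength=n_max + 1) / n_samples
    return HitDistribution(pmf)
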