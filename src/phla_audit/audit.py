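"""Dataset-level bias audit: coverage across populations and income statistics.

Computes sPC90 for a dataset against every retained geographic population,
groups the values by the income level of each population's country, and tests
whether the distributions differ: a one-way ANOVA across the four income
groups, followed by one-sided two-sample Kolmogorov-Smirnov tests over all
income-level pairs asking whether the poorer group's sPC90 values are
stochastically smaller than the richer group's.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageResult, population_coverage
from .datasets import PHLADataset
from .frequencies import FrequencyTable
from .income import INCOME_LEVELS
from .nomenclature import CLASS_I_LOCI

logger = logging.getLogger(__name__)

_SMALL_SAMPLE = 10  # below this the asymptotic KS p-value is unreliable


def audit_coverage(
    dataset: PHLADataset,
    table: FrequencyTable,
    q: float = 0.90,
    interpolate: bool = False,
    loci: tuple[str, ...] = CLASS_I_LOCI,
) -> list[CoverageResult]:
    """One :class:`CoverageResult` per retained population.

    ``dataset`` must be mono-allelic (deconvolute MS data first); the
    frequency table must already be validated and complete-loci filtered.
    """
    pairs = dataset.unique_pairs()
    results = []
    for population in table.populations:
        info = table.population_info(population)
        freqs = {locus: table.locus_frequencies(population, locus) for locus in loci}
        freqs = {locus: f for locus, f in freqs.items() if f}
        results.append(
            population_coverage(
                pairs,
                freqs,
                population=population,
                country=info["country"],
                income_level=info["income_level"],
                q=q,
                interpolate=interpolate,
                loci=loci,
            )
        )
    return results


def coverage_frame(results: list[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population": r.population,
            "country": r.country,
            "income_level": r.income_level,
            "coverage": r.coverage,
            "pc90": r.pc90,
            "spc90": r.spc90,
            "dataset_size": r.dataset_size,
        }
        for r in results
    )


def group_by_income(results: list[CoverageResult]) -> dict[str, list[float]]:
    """sPC90 values grouped by income level (unclassified populations dropped)."""
    groups: dict[str, list[float]] = {level: [] for level in INCOME_LEVELS}
    for r in results:
        if r.income_level in groups:
            groups[r.income_level].append(r.spc90)
    return {level: values for level, values in groups.items() if values}


def anova_one_way(groups: dict[str, list[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and upper-tail p-value across the groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for level, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {level!r} has fewer than two values")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if np.ptp(np.concatenate(values)) == 0:
        return 0.0, 1.0  # no variance anywhere: zero between-group mean square
    f, p = stats.f_oneway(*values)
    return float(f), float(p)


def ks_one_sided(
    sample_a: np.ndarray, sample_b: np.ndarray, direction: str = "a_below_b"
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test.

    ``direction='a_below_b'`` tests the alternative that sample_a is
    stochastically smaller than sample_b, i.e. ECDF_a lies above ECDF_b;
    D is the supremum of ECDF_a - ECDF_b. ``'a_above_b'`` is the mirror
    image. The p-value is the one-sided asymptotic tail
    exp(-2 m n D^2 / (m + n)), flagged as unreliable when min(m, n) < 10.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs nonempty samples")
    if direction not in ("a_below_b", "a_above_b"):
        raise ValueError(f"unknown direction {direction!r}")
    grid = np.concatenate([a, b])
    ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    diff = ecdf_a - ecdf_b if direction == "a_below_b" else ecdf_b - ecdf_a
    d = float(max(diff.max(), 0.0))
    m, n = a.size, b.size
    if min(m, n) < _SMALL_SAMPLE:
        logger.warning(
            "KS samples of size (%d, %d): asymptotic p-value unreliable below n=%d",
            m,
            n,
            _SMALL_SAMPLE,
        )
    p = float(np.exp(-2.0 * m * n * d**2 / (m + n)))
    return d, min(p, 1.0)


@dataclass
class GroupStats:
    """Income-group comparison of sPC90 distributions."""

    groups: dict[str, list[float]]
    anova_f: float
    anova_p: float
    ks_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "groups": {k: list(map(float, v)) for k, v in self.groups.items()},
            "anova": {"F": self.anova_f, "p": self.anova_p},
            "ks_pairwise": self.ks_pairs.to_dict(orient="records"),
        }


def income_group_stats(results: list[CoverageResult]) -> GroupStats:
    """ANOVA plus pairwise one-sided KS over income levels, poorest first.

    Each KS pair tests whether the lower-income group's sPC90 values are
    stochastically smaller than the higher-income group's. Pairwise p-values
    are reported raw and Holm-adjusted.
    """
    groups = group_by_income(results)
    f, p = anova_one_way(groups)
    ordered = [level for level in INCOME_LEVELS if level in groups]
    rows = []
    for lower, higher in itertools.combinations(ordered, 2):
        d, ks_p = ks_one_sided(
            np.array(groups[lower]), np.array(groups[higher]), "a_below_b"
        )
        rows.append(
            {
                "lower_income": lower,
                "higher_income": higher,
                "D": d,
                "p": ks_p,
                "n_lower": len(groups[lower]),
                "n_higher": len(groups[higher]),
            }
        )
    ks = pd.DataFrame(rows)
    if not ks.empty:
        ks["p_holm"] = multipletests(ks["p"], method="holm")[1]
    return GroupStats(groups=groups, anova_f=f, anova_p=p, ks_pairs=ks)
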