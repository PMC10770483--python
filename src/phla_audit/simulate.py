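"""Synthetic inputs for the audit pipeline.

Generates all four inputs the pipeline consumes — multi-population allele
frequency tables, income classification tables, pHLA datasets with a
controllable income-correlated allele bias, and random proteomes — plus a
mock predictor with controllable per-allele accuracy. Together these emulate
the statistical structure of the real inputs (long-tailed per-allele counts,
overrepresentation of alleles common in high-income populations, per-allele
performance differences) without any download, so every stage of the audit is
testable end to end.

The frequency model draws each population-locus block from a symmetric
Dirichlet; small concentration values give the long-tailed frequency spectra
typical of HLA loci. Dataset bias is a single exponent beta >= 1 applied to
each allele's mean frequency among high-income populations: beta = 1 samples
alleles in proportion to those frequencies, larger beta concentrates the
dataset on the alleles most common in high-income countries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import AMINO_ACIDS, MAX_CANDIDATES, PHLADataset, PHLARecord
from .frequencies import FrequencyTable
from .income import INCOME_LEVELS
from .nomenclature import CLASS_I_LOCI

# representative GNI per capita (USD) inside each World Bank band
_GNI_BY_LEVEL = {"low": 800.0, "lower-middle": 2600.0, "upper-middle": 8500.0, "high": 42000.0}


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic audit scenario.

    Defaults describe a modest desk-scale study: 5 populations per income
    level (20 total), 12 alleles at each of the A, B and C loci with
    long-tailed Dirichlet(0.5) frequencies, a 2,000-record dataset of 8-11mer
    peptides of which 30% are multi-allelic, and no bias (beta = 1).
    ``bias`` is the overrepresentation exponent of high-income-common
    alleles; ``separation`` maps alleles to the mock predictor's score
    separation d_a >= 0 between their binders and background peptides.
    """

    populations_per_income: int = 5
    alleles_per_locus: int = 12
    loci: tuple[str, ...] = CLASS_I_LOCI
    concentration: float = 0.5
    dataset_size: int = 2000
    bias: float = 1.0
    multiallelic_fraction: float = 0.3
    peptide_lengths: tuple[int, ...] = (8, 9, 10, 11)
    separation: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.populations_per_income < 1 or self.alleles_per_locus < 1:
            raise ValueError("counts must be >= 1")
        if self.dataset_size < 1:
            raise ValueError("dataset_size must be >= 1")
        if self.bias < 1.0:
            raise ValueError("bias exponent must be >= 1")
        if not 0.0 <= self.multiallelic_fraction <= 1.0:
            raise ValueError("multiallelic_fraction must be in [0, 1]")
        if any(d < 0 for d in self.separation.values()):
            raise ValueError("separation values must be >= 0")

    def allele_names(self) -> list[str]:
        return [
            f"{locus}*{i + 1:02d}:01"
            for locus in self.loci
            for i in range(self.alleles_per_locus)
        ]

    def to_dict(self) -> dict:
        return asdict(self)


def gen_income_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Country -> GNI-per-capita classification table for the scenario.

    One synthetic country per population, with a GNI value placed inside the
    country's World Bank band.
    """
    rows = []
    for level in INCOME_LEVELS:
        for k in range(spec.populations_per_income):
            rows.append(
                {
                    "country": f"{level.title()}land-{k + 1}",
                    "gni_per_capita": _GNI_BY_LEVEL[level] + 10 * k,
                    "income_level": level,
                }
            )
    return pd.DataFrame(rows)


def gen_frequency_table(spec: ScenarioSpec) -> FrequencyTable:
    """Allele-frequency table over all scenario populations.

    Each (population, locus) block is an independent draw from a symmetric
    Dirichlet with the scenario's concentration, so frequencies sum to 1 by
    construction. Population labels embed the country name, and country and
    income annotations are attached directly.
    """
    rng = np.random.default_rng(spec.seed)
    income = gen_income_table(spec)
    rows = []
    for rec in income.itertuples():
        population = f"{rec.country} General"
        for locus in spec.loci:
            freqs = rng.dirichlet(np.full(spec.alleles_per_locus, spec.concentration))
            for i, f in enumerate(freqs):
                rows.append(
                    {
                        "population": population,
                        "country": rec.country,
                        "locus": locus,
                        "allele": f"{locus}*{i + 1:02d}:01",
                        "frequency": float(f),
                        "sample_size": int(rng.integers(50, 5000)),
                        "income_level": rec.income_level,
                    }
                )
    return FrequencyTable(pd.DataFrame(rows))


def _high_income_weights(spec: ScenarioSpec, table: FrequencyTable) -> pd.Series:
    """Dataset sampling weight per allele: (mean high-income frequency)^beta."""
    frame = table.frame
    high = frame[frame["income_level"] == "high"]
    if high.empty:
        high = frame
    mean_freq = high.groupby("allele")["frequency"].mean()
    mean_freq = mean_freq.reindex(spec.allele_names(), fill_value=0.0)
    w = mean_freq.to_numpy() ** spec.bias
    return pd.Series(w / w.sum(), index=mean_freq.index)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_phla_dataset(
    spec: ScenarioSpec, table: FrequencyTable
) -> tuple[PHLADataset, pd.Series]:
    """Sample a pHLA dataset whose allele composition follows the bias model.

    Each record's presenting allele is drawn from the high-income-weighted
    distribution; the configured fraction of records is made multi-allelic by
    adding 1-5 extra candidate alleles (an MS sample's other class I alleles).
    Returns the dataset and the generator's own tally of presenting alleles —
    the bookkeeping oracle for per-allele count checks.
    """
    rng = np.random.default_rng(spec.seed + 1)
    weights = _high_income_weights(spec, table)
    alleles = np.asarray(weights.index)
    records = []
    tally = pd.Series(0, index=weights.index, dtype=int)
    for _ in range(spec.dataset_size):
        presenting = str(rng.choice(alleles, p=weights.to_numpy()))
        tally[presenting] += 1
        length = int(rng.choice(spec.peptide_lengths))
        peptide = random_peptide(rng, length)
        if rng.random() < spec.multiallelic_fraction and len(alleles) > 1:
            n_extra = int(rng.integers(1, MAX_CANDIDATES))
            others = [a for a in alleles if a != presenting]
            extra = rng.choice(others, size=min(n_extra, len(others)), replace=False)
            candidates = (presenting, *map(str, extra))
            records.append(PHLARecord(peptide, candidates, assay="MS"))
        else:
            assay = "MS" if rng.random() < 0.5 else "BA"
            records.append(PHLARecord(peptide, (presenting,), assay=assay))
    return PHLADataset(records), tally


def gen_proteome(
    total_length: int, seed: int = 0, n_sequences: int = 10
) -> list[SeqRecord]:
    """Random protein sequences totalling ``total_length`` residues.

    A stand-in for a real proteome as a decoy source: i.i.d. uniform residues
    over the 20-letter alphabet, split into ``n_sequences`` records.
    """
    if total_length < 11:
        raise ValueError("proteome must be at least 11 residues long")
    rng = np.random.default_rng(seed)
    n_sequences = min(n_sequences, max(1, total_length // 11))
    bounds = np.linspace(0, total_length, n_sequences + 1).astype(int)
    records = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=b - a))
        records.append(
            SeqRecord(Seq(seq), id=f"synthetic_protein_{i + 1}", description=f"seed={seed}")
        )
    return records


def _hash_normal(peptide: str, allele: str, seed: int) -> float:
    """Deterministic standard-normal draw keyed by (peptide, allele, seed)."""
    digest = hashlib.blake2b(
        f"{peptide}|{allele}|{seed}".encode(), digest_size=8
    ).digest()
    u = (int.from_bytes(digest, "big") + 0.5) / 2**64  # uniform in (0, 1)
    return float(ndtri(u))


class MockPredictor:
    """Deterministic scoring oracle with controllable per-allele accuracy.

    The strength of a designated true binder of allele ``a`` is distributed
    Normal(d_a, 1) and every other (peptide, allele) query Normal(0, 1),
    realised deterministically by hashing (peptide, allele, seed). The
    percentile rank is the upper tail of the Normal(0, 1) background in
    percent — a frozen decoy-score reference — so rank decreases strictly as
    strength increases and the adapter contract holds exactly.
    """

    def __init__(
        self,
        separation: dict[str, float] | None = None,
        binders: set[tuple[str, str]] | None = None,
        seed: int = 0,
    ):
        self.separation = dict(separation or {})
        if any(d < 0 for d in self.separation.values()):
            raise ValueError("separation values must be >= 0")
        self.binders = set(binders or ())
        self.seed = seed

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        strength = _hash_normal(peptide, allele, self.seed)
        if (peptide, allele) in self.binders:
            strength += self.separation.get(allele, 0.0)  # unknown allele: d_a = 0
        rank = 100.0 * float(ndtr(-strength))  # upper tail of the N(0,1) background
        return strength, rank


def mock_predictor_for(
    dataset: PHLADataset,
    separation: dict[str, float] | None = None,
    seed: int = 0,
) -> MockPredictor:
    """Mock predictor whose true binders are the dataset's presenting alleles.

    Each record's first candidate is its presenting allele by construction of
    :func:`gen_phla_dataset`, so designating (peptide, first candidate) pairs
    as true binders gives deconvolution and evaluation coherent signal for the
    alleles with nonzero separation.
    """
    binders = {(record.peptide, record.alleles[0]) for record in dataset}
    return MockPredictor(separation=separation, binders=binders, seed=seed)
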