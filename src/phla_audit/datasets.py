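"""pHLA dataset containers: peptide-allele records from BA and MS assays.

Binding-affinity (BA) records pair one peptide with one allele. Mass
spectrometry eluted-ligand (MS) records may be multi-allelic: the peptide was
eluted from a sample expressing up to six class I alleles (two each at A, B,
C) and any of them could be the presenting allele, so deconvolution is
required before per-allele analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_CANDIDATES = 6
ASSAYS = ("BA", "MS")

_ALLELE_SEP = ";"


@dataclass(frozen=True)
class PHLARecord:
    """One peptide with its candidate allele(s)."""

    peptide: str
    alleles: tuple[str, ...]
    assay: str = "MS"
    label: float | None = None  # binder flag or affinity; None for elution data

    def __post_init__(self) -> None:
        if not set(self.peptide) <= set(AMINO_ACIDS):
            bad = sorted(set(self.peptide) - set(AMINO_ACIDS))
            raise ValueError(f"peptide {self.peptide!r} has non-standard residues {bad}")
        if not 1 <= len(self.alleles) <= MAX_CANDIDATES:
            raise ValueError(
                f"record must carry 1-{MAX_CANDIDATES} candidate alleles, "
                f"got {len(self.alleles)}"
            )
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alleles) > 1


@dataclass
class PHLADataset:
    """An audited epitope set: a list of records plus tabular round-trips."""

    records: list[PHLARecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def is_monoallelic(self) -> bool:
        return all(not r.is_multiallelic for r in self.records)

    def unique_pairs(self) -> list[tuple[str, str]]:
        """Unique (peptide, allele) pairs of a mono-allelic dataset.

        This is the input unit of the coverage computation and the dataset
        size N used for sPC90.
        """
        if not self.is_monoallelic:
            raise ValueError("deconvolute multi-allelic records before taking pairs")
        return list(dict.fromkeys((r.peptide, r.alleles[0]) for r in self.records))

    def peptide_lengths(self) -> list[int]:
        return sorted({len(r.peptide) for r in self.records})

    def binders_by_allele(self) -> dict[str, list[str]]:
        """Allele -> peptides map of a mono-allelic dataset (unique pairs)."""
        out: dict[str, list[str]] = {}
        for pep, allele in self.unique_pairs():
            out.setdefault(allele, []).append(pep)
        return out

    # -------------------------------------------------------------- tabular
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide": [r.peptide for r in self.records],
                "alleles": [_ALLELE_SEP.join(r.alleles) for r in self.records],
                "assay": [r.assay for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PHLADataset":
        records = [
            PHLARecord(
                peptide=str(row.peptide),
                alleles=tuple(str(row.alleles).split(_ALLELE_SEP)),
                assay=str(getattr(row, "assay", "MS")),
                label=None if pd.isna(getattr(row, "label", None)) else float(row.label),
            )
            for row in frame.itertuples()
        ]
        return cls(records)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "PHLADataset":
        return cls.from_frame(pd.read_csv(path, sep=sep, engine="python"))


def per_allele_counts(dataset: PHLADataset) -> pd.Series:
    """Number of data points per allele, sorted by descending count.

    Requires mono-allelic records (apply deconvolution to MS data first);
    counts sum to the dataset size.
    """
    if not dataset.is_monoallelic:
        raise ValueError("per-allele counts need mono-allelic records")
    counts = Counter(r.alleles[0] for r in dataset.records)
    series = pd.Series(counts, dtype=int, name="count")
    return series.sort_values(ascending=False, kind="stable")
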