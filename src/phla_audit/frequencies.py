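"""Population allele-frequency tables: ingestion, validation, annotation.

A frequency table holds, per geographic population and HLA locus, the allele
frequencies estimated by population studies (the structure of the Allele
Frequency Net Database). Before any coverage computation the table is
canonicalized, deduplicated, checked so every (population, locus) block sums
to 1, and restricted to populations typed at every configured locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .income import (
    UNCLASSIFIED,
    IncomeThresholds,
    classify_income,
    extract_country,
)
from .nomenclature import CLASS_I_LOCI, OTHER_ALLELE, canonical_str

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("population", "country", "locus", "allele", "frequency")


@dataclass
class ValidationReport:
    """Outcome of the sum-to-1 sanity check, one row per (population, locus)."""

    sums: pd.DataFrame  # columns: population, locus, total, status
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __str__(self) -> str:
        n_bad = len(self.excluded)
        return f"ValidationReport: {len(self.sums)} population-locus sums, {n_bad} excluded"


class FrequencyTable:
    """Per-population, per-locus allele -> frequency map with annotations.

    Thin wrapper over a tidy :class:`pandas.DataFrame` with columns
    ``population, country, locus, allele, frequency`` plus optional
    ``sample_size`` and, after :meth:`annotate_income`, ``income_level``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"frequency table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "FrequencyTable":
        """Read a delimited text table (TSV or CSV; delimiter sniffed)."""
        frame = pd.read_csv(path, sep=sep, engine="python")
        return cls(frame)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    # ------------------------------------------------------------ pipeline
    def canonicalize(self, loci: tuple[str, ...] = CLASS_I_LOCI) -> "FrequencyTable":
        """Canonicalize allele names to two fields; rederive the locus column."""
        frame = self.frame.copy()
        mask = frame["allele"] != OTHER_ALLELE
        frame.loc[mask, "allele"] = frame.loc[mask, "allele"].map(
            lambda a: canonical_str(a, loci)
        )
        frame["locus"] = frame["allele"].str.split("*").str[0].where(mask, frame["locus"])
        return FrequencyTable(frame)

    def dedupe(self, rule: str = "largest_sample") -> tuple["FrequencyTable", pd.DataFrame]:
        """Drop duplicate (population, allele) entries.

        ``rule='largest_sample'`` keeps the entry with the largest reported
        ``sample_size`` (first in file order when sample sizes are absent or
        tied); ``rule='first'`` always keeps the first occurrence. Returns the
        deduplicated table and a log of removed rows with conflicting
        frequencies flagged.
        """
        frame = self.frame.copy()
        key = ["population", "allele"]
        dup_mask = frame.duplicated(key, keep=False)
        if not dup_mask.any():
            return FrequencyTable(frame), frame.iloc[0:0].assign(conflict=pd.Series(dtype=bool))

        frame["_order"] = np.arange(len(frame))
        if rule == "largest_sample" and "sample_size" in frame.columns:
            # stable sort: larger sample first, original order breaks ties
            size = frame["sample_size"].fillna(-np.inf)
            order = np.lexsort((frame["_order"].to_numpy(), -size.to_numpy()))
            ranked = frame.iloc[order]
        elif rule in ("largest_sample", "first"):
            ranked = frame
        else:
            raise ValueError(f"unknown duplicate rule {rule!r}")

        keep_idx = ranked.drop_duplicates(key, keep="first").index
        removed = frame.loc[~frame.index.isin(keep_idx)].copy()
        kept = frame.loc[frame.index.isin(keep_idx)].sort_values("_order")

        kept_freq = kept.set_index(key)["frequency"]
        removed["conflict"] = [
            not np.isclose(row.frequency, kept_freq.loc[(row.population, row.allele)])
            for row in removed.itertuples()
        ]
        for row in removed.itertuples():
            if row.conflict:
                logger.warning(
                    "duplicate (%s, %s): dropped frequency %g in favor of %g",
                    row.population,
                    row.allele,
                    row.frequency,
                    kept_freq.loc[(row.population, row.allele)],
                )
        return (
            FrequencyTable(kept.drop(columns="_order")),
            removed.drop(columns="_order").reset_index(drop=True),
        )

    def validate(
        self,
        tolerance: float = 0.05,
        renormalize: bool = True,
    ) -> tuple["FrequencyTable", ValidationReport]:
        """Check that every (population, locus) block sums to 1.

        Sums within ``tolerance`` of 1 are fixed up: proportionally rescaled
        when ``renormalize`` is true, otherwise a deficit ``1 - s`` is parked
        on the synthetic ``OTHER`` allele (which can never be hit by a dataset
        pair), preserving probability mass for the coverage math. Sums outside
        tolerance flag the (population, locus) for exclusion.
        """
        frame = self.frame.copy()
        records, excluded, keep_parts = [], [], []
        for (pop, locus), block in frame.groupby(["population", "locus"], sort=False):
            total = float(block["frequency"].sum())
            if abs(total - 1.0) > tolerance:
                records.append((pop, locus, total, "excluded"))
                excluded.append((pop, locus))
                continue
            block = block.copy()
            if renormalize:
                block["frequency"] = block["frequency"] / total
                status = "renormalized" if not np.isclose(total, 1.0) else "ok"
            elif total < 1.0 and not np.isclose(total, 1.0):
                other = block.iloc[[0]].copy()
                other["allele"] = OTHER_ALLELE
                other["frequency"] = 1.0 - total
                if "sample_size" in other.columns:
                    other["sample_size"] = np.nan
                block = pd.concat([block, other])
                status = "residual_to_other"
            elif total > 1.0 and not np.isclose(total, 1.0):
                # excess mass cannot be parked on OTHER; rescale down
                block["frequency"] = block["frequency"] / total
                status = "renormalized"
            else:
                status = "ok"
            records.append((pop, locus, total, status))
            keep_parts.append(block)

        sums = pd.DataFrame(records, columns=["population", "locus", "total", "status"])
        out = (
            pd.concat(keep_parts, ignore_index=True)
            if keep_parts
            else frame.iloc[0:0]
        )
        return FrequencyTable(out), ValidationReport(sums=sums, excluded=excluded)

    def filter_complete_loci(self, loci: tuple[str, ...] = CLASS_I_LOCI) -> "FrequencyTable":
        """Keep only populations typed at every locus in ``loci``."""
        have = self.frame.groupby("population")["locus"].agg(set)
        complete = have[have.map(lambda s: set(loci) <= s)].index
        return FrequencyTable(self.frame[self.frame["population"].isin(complete)])

    def annotate_income(
        self,
        income_table: pd.DataFrame,
        thresholds: IncomeThresholds = IncomeThresholds(),
        overrides: dict[str, str] | None = None,
    ) -> "FrequencyTable":
        """Attach an ``income_level`` column via the country of each population.

        Rows whose ``country`` is empty are resolved by longest-match of the
        population label against the classification table's country names.
        Unresolvable populations get the explicit ``unclassified`` status.
        """
        frame = self.frame.copy()
        known = income_table["country"].astype(str).tolist()

        def country_of(row) -> str:
            c = row["country"]
            if isinstance(c, str) and c.strip():
                return c
            found = extract_country(str(row["population"]), known, overrides)
            return found if found is not None else ""

        frame["country"] = frame.apply(country_of, axis=1)
        levels = {
            c: classify_income(c, income_table, thresholds) if c else UNCLASSIFIED
            for c in frame["country"].unique()
        }
        frame["income_level"] = frame["country"].map(levels)
        return FrequencyTable(frame)

    # ------------------------------------------------------------ accessors
    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.frame["population"]))

    def locus_frequencies(self, population: str, locus: str) -> dict[str, float]:
        """Allele -> frequency map for one population and locus."""
        block = self.frame[
            (self.frame["population"] == population) & (self.frame["locus"] == locus)
        ]
        return dict(zip(block["allele"], block["frequency"].astype(float)))

    def population_info(self, population: str) -> dict:
        row = self.frame[self.frame["population"] == population].iloc[0]
        return {
            "population": population,
            "country": row.get("country", ""),
            "income_level": row.get("income_level", UNCLASSIFIED),
        }

    def __len__(self) -> int:
        return len(self.frame)


def clean_frequency_table(
    table: FrequencyTable,
    loci: tuple[str, ...] = CLASS_I_LOCI,
    sum_tolerance: float = 0.05,
    renormalize: bool = True,
    duplicate_rule: str = "largest_sample",
) -> tuple[FrequencyTable, ValidationReport, pd.DataFrame]:
    """Full cleaning pipeline: canonicalize, dedupe, validate, complete-loci filter."""
    table = table.canonicalize(loci)
    table, removed = table.dedupe(duplicate_rule)
    table, report = table.validate(sum_tolerance, renormalize)
    table = table.filter_complete_loci(loci)
    return table, report, removed
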