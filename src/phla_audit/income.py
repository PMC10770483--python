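"""National income classification of geographic populations.

Populations in allele-frequency tables are labelled with a geographic
designation (usually a country plus an optional ancestry tag, e.g.
"USA Hispanic"). The audit groups populations by the World Bank's four-way
national income classification — low, lower-middle, upper-middle, high —
defined by GNI (gross national income) per capita ceilings.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Ordered from poorest to richest; order matters for reporting and KS pairs.
INCOME_LEVELS = ("low", "lower-middle", "upper-middle", "high")

#: Status returned when a country cannot be resolved; never a silent default.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class IncomeThresholds:
    """GNI-per-capita ceilings (current USD) separating the four levels.

    Defaults follow the World Bank 2022-2023 classification: low-income up to
    $1,085; lower-middle up to $4,255; upper-middle up to $13,205; high above.
    """

    low_ceiling: float = 1085.0
    lower_middle_ceiling: float = 4255.0
    upper_middle_ceiling: float = 13205.0

    def __post_init__(self) -> None:
        if not (self.low_ceiling < self.lower_middle_ceiling < self.upper_middle_ceiling):
            raise ValueError("income ceilings must be strictly increasing")


def classify_gni(gni: float, thresholds: IncomeThresholds = IncomeThresholds()) -> str:
    """Map a GNI-per-capita value to exactly one income level."""
    if gni < 0:
        raise ValueError(f"GNI per capita must be nonnegative, got {gni}")
    if gni <= thresholds.low_ceiling:
        return "low"
    if gni <= thresholds.lower_middle_ceiling:
        return "lower-middle"
    if gni <= thresholds.upper_middle_ceiling:
        return "upper-middle"
    return "high"


def classify_income(
    country: str,
    income_table: pd.DataFrame,
    thresholds: IncomeThresholds = IncomeThresholds(),
) -> str:
    """Income level of a country from a classification table.

    ``income_table`` needs a ``country`` column and either a precomputed
    ``income_level`` column or a ``gni_per_capita`` column. Matching is
    case-insensitive on the full country name. An unknown country returns
    :data:`UNCLASSIFIED`.
    """
    rows = income_table[income_table["country"].str.casefold() == country.casefold()]
    if rows.empty:
        return UNCLASSIFIED
    row = rows.iloc[0]
    if "income_level" in income_table.columns and pd.notna(row.get("income_level")):
        level = str(row["income_level"])
        if level not in INCOME_LEVELS:
            raise ValueError(f"unrecognized income level {level!r} for {country!r}")
        return level
    if "gni_per_capita" not in income_table.columns:
        raise ValueError("income table needs an income_level or gni_per_capita column")
    return classify_gni(float(row["gni_per_capita"]), thresholds)


def extract_country(
    label: str,
    known_countries: list[str] | pd.Series,
    overrides: dict[str, str] | None = None,
) -> str | None:
    """Resolve the country named inside a population label.

    Uses the longest case-insensitive match against the classification table's
    country names, so "South Africa Zulu" resolves to "South Africa" rather
    than "Africa" if both appear. ``overrides`` maps ambiguous raw labels
    directly to a country and wins over matching.
    """
    if overrides and label in overrides:
        return overrides[label]
    folded = label.casefold()
    best: str | None = None
    for country in known_countries:
        c = str(country)
        if c.casefold() in folded and (best is None or len(c) > len(best)):
            best = c
    return best
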