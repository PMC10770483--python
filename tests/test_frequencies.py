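"""Frequency-table cleaning: dedup, sum-to-1 validation, locus completeness,
and income classification."""

import numpy as np
import pandas as pd
import pytest

from phla_audit.frequencies import FrequencyTable, clean_frequency_table
from phla_audit.income import (
    UNCLASSIFIED,
    IncomeThresholds,
    classify_gni,
    classify_income,
    extract_country,
)
from phla_audit.nomenclature import OTHER_ALLELE


def _table(rows, columns=("population", "country", "locus", "allele", "frequency", "sample_size")):
    return FrequencyTable(pd.DataFrame(rows, columns=list(columns)))


class TestDedupe:
    def test_identical_rows_collapse_to_one(self):
        t = _table(
            [
                ("PopX", "X", "A", "A*01:01", 0.3, 100),
                ("PopX", "X", "A", "A*01:01", 0.3, 100),
            ]
        )
        out, removed = t.dedupe()
        assert len(out) == 1
        assert len(removed) == 1 and not removed["conflict"].any()

    def test_conflict_resolved_by_larger_sample_size_and_logged(self):
        t = _table(
            [
                ("PopX", "X", "A", "A*01:01", 0.3, 100),
                ("PopX", "X", "A", "A*01:01", 0.4, 500),
            ]
        )
        out, removed = t.dedupe()
        assert len(out) == 1
        assert out.frame["frequency"].iloc[0] == 0.4
        assert removed["conflict"].all()

    def test_first_wins_without_sample_sizes(self):
        t = _table(
            [
                ("PopX", "X", "A", "A*01:01", 0.3),
                ("PopX", "X", "A", "A*01:01", 0.4),
            ],
            columns=("population", "country", "locus", "allele", "frequency"),
        )
        out, _ = t.dedupe()
        assert out.frame["frequency"].iloc[0] == 0.3

    def test_no_duplicates_is_a_noop_and_rerun_idempotent(self, small_frequency_table):
        out, removed = small_frequency_table.dedupe()
        assert removed.empty
        pd.testing.assert_frame_equal(out.frame, small_frequency_table.frame)
        again, _ = out.dedupe()
        assert len(again) <= len(out)
        pd.testing.assert_frame_equal(again.frame, out.frame)


class TestValidate:
    def test_exact_sum_passes(self):
        t = _table([("P", "X", "A", "A*01:01", 0.5, 1), ("P", "X", "A", "A*02:01", 0.5, 1)])
        out, report = t.validate(tolerance=0.05)
        assert report.sums["status"].tolist() == ["ok"]
        assert len(out) == 2

    def test_out_of_tolerance_locus_is_excluded(self):
        t = _table([("P", "X", "A", "A*01:01", 0.6, 1), ("P", "X", "A", "A*02:01", 0.5, 1)])
        out, report = t.validate(tolerance=0.05)
        assert ("P", "A") in report.excluded
        assert len(out) == 0

    def test_within_tolerance_renormalizes_to_exactly_one(self):
        t = _table([("P", "X", "A", "A*01:01", 0.58, 1), ("P", "X", "A", "A*02:01", 0.39, 1)])
        out, report = t.validate(tolerance=0.05, renormalize=True)
        assert report.sums["status"].tolist() == ["renormalized"]
        assert out.frame["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_deficit_goes_to_other_when_renormalization_disabled(self):
        t = _table([("P", "X", "A", "A*01:01", 0.58, 1), ("P", "X", "A", "A*02:01", 0.39, 1)])
        out, report = t.validate(tolerance=0.05, renormalize=False)
        other = out.frame[out.frame["allele"] == OTHER_ALLELE]
        assert len(other) == 1
        assert other["frequency"].iloc[0] == pytest.approx(0.03)
        assert out.frame["frequency"].sum() == pytest.approx(1.0, abs=1e-12)
        assert report.sums["status"].tolist() == ["residual_to_other"]


class TestCompleteLoci:
    def test_incomplete_population_dropped(self, small_frequency_table):
        out = small_frequency_table.filter_complete_loci(("A", "B"))
        assert out.populations == ["Popland General"]

    def test_complete_population_retained_and_single_locus_config(self, small_frequency_table):
        out = small_frequency_table.filter_complete_loci(("A",))
        assert set(out.populations) == {"Popland General", "Otherland General"}

    def test_abc_requirement_drops_ab_only_population(self, small_frequency_table):
        out = small_frequency_table.filter_complete_loci(("A", "B", "C"))
        assert out.populations == []


def test_clean_pipeline_retained_blocks_sum_to_one(rng):
    rows = []
    for p in range(6):
        for locus in "ABC":
            k = int(rng.integers(1, 5))
            f = rng.dirichlet(np.ones(k)) * rng.uniform(0.9, 1.1)
            for i, freq in enumerate(f):
                rows.append((f"Pop{p}", f"Country{p}", locus, f"{locus}*{i+1:02d}:01", freq, 10))
    out, report, _ = clean_frequency_table(_table(rows), sum_tolerance=0.05)
    sums = out.frame.groupby(["population", "locus"])["frequency"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    for pop in out.populations:
        assert set(out.frame[out.frame["population"] == pop]["locus"]) == set("ABC")


class TestIncome:
    @pytest.mark.parametrize(
        "gni, level",
        [
            (900, "low"),
            (1085, "low"),
            (1086, "lower-middle"),
            (4255, "lower-middle"),
            (4256, "upper-middle"),
            (13205, "upper-middle"),
            (13206, "high"),
            (50000, "high"),
        ],
    )
    def test_gni_bands(self, gni, level):
        assert classify_gni(gni) == level

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            IncomeThresholds(low_ceiling=5000, lower_middle_ceiling=4000)

    def test_unknown_country_is_explicitly_unclassified(self):
        table = pd.DataFrame({"country": ["Popland"], "gni_per_capita": [900]})
        assert classify_income("Popland", table) == "low"
        assert classify_income("Atlantis", table) == UNCLASSIFIED

    def test_precomputed_level_wins_over_gni(self):
        table = pd.DataFrame(
            {"country": ["Popland"], "gni_per_capita": [900], "income_level": ["high"]}
        )
        assert classify_income("Popland", table) == "high"

    def test_country_extraction_prefers_longest_match(self):
        countries = ["Africa", "South Africa", "Iran"]
        assert extract_country("South Africa Zulu", countries) == "South Africa"
        assert extract_country("Iran Kurd", countries) == "Iran"
        assert extract_country("Nowhere Pop", countries) is None
        assert extract_country("Ambiguous", countries, {"Ambiguous": "Iran"}) == "Iran"

    def test_annotate_income_attaches_levels(self, small_frequency_table):
        income = pd.DataFrame(
            {"country": ["Popland", "Otherland"], "gni_per_capita": [900, 50000]}
        )
        out = small_frequency_table.annotate_income(income)
        levels = out.frame.groupby("country")["income_level"].first()
        assert levels["Popland"] == "low"
        assert levels["Otherland"] == "high"
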