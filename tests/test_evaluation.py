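"""Predictor evaluation: deconvolution, decoy sampling, PPV and FOOP."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phla_audit.datasets import PHLADataset, PHLARecord
from phla_audit.evaluation import (
    PredictorError,
    ScoreTablePredictor,
    deconvolute,
    decoys_per_length,
    evaluate_predictor,
    foop_from_scores,
    foop_per_allele,
    ppv_from_scores,
    ppv_per_allele,
    sample_decoys,
)
from phla_audit.simulate import MockPredictor, gen_proteome


def _records(*allele_sets):
    # distinct peptides over the standard alphabet: PEPTIDEA, PEPTIDEC, ...
    return PHLADataset(
        [
            PHLARecord("PEPTIDE" + "ACDEFGHIKL"[i], alleles)
            for i, alleles in enumerate(allele_sets)
        ]
    )


class TestDeconvolution:
    def test_lowest_rank_candidate_wins(self):
        ds = _records(("A*01:01", "B*07:02"))
        pred = ScoreTablePredictor(
            strengths={("PEPTIDEA", "A*01:01"): 5.0, ("PEPTIDEA", "B*07:02"): 4.0},
            ranks={("PEPTIDEA", "A*01:01"): 0.1, ("PEPTIDEA", "B*07:02"): 0.3},
        )
        out, log = deconvolute(ds, pred)
        assert out.records[0].alleles == ("A*01:01",)
        assert log.n_kept == 1

    @pytest.mark.parametrize("best_rank, kept", [(0.7, 0), (0.5, 0), (0.49, 1)])
    def test_rank_cutoff_is_inclusive(self, best_rank, kept):
        ds = _records(("A*01:01",))
        pred = ScoreTablePredictor(
            strengths={("PEPTIDEA", "A*01:01"): 1.0},
            ranks={("PEPTIDEA", "A*01:01"): best_rank},
        )
        out, log = deconvolute(ds, pred)
        assert len(out) == kept
        assert log.n_excluded_rank == 1 - kept

    def test_failure_is_flagged_not_dropped_silently(self):
        ds = _records(("A*01:01",), ("B*07:02",))
        pred = ScoreTablePredictor(
            strengths={("PEPTIDEC", "B*07:02"): 1.0},
            ranks={("PEPTIDEC", "B*07:02"): 0.01},
        )
        out, log = deconvolute(ds, pred)
        assert len(log.failed) == 1
        assert log.failed[0].peptide == "PEPTIDEA"
        assert len(out) == 1

    def test_output_subset_of_candidates_and_size_bounded(self):
        ds = _records(("A*01:01", "B*07:02", "C*04:01"), ("A*02:01", "A*03:01"))
        pred = MockPredictor(seed=5)
        out, _ = deconvolute(ds, pred, rank_cutoff=100.0)  # keep everything
        assert len(out) <= len(ds)
        for rec_in, rec_out in zip(ds, out):
            assert rec_out.alleles[0] in rec_in.alleles
            assert not rec_out.is_multiallelic


class TestDecoys:
    def test_single_window_proteome(self):
        proteome = [SeqRecord(Seq("ACDEFGHIK"), id="p1")]
        decoys = sample_decoys(proteome, length=9, n_decoys=5, seed=0)
        assert decoys == ["ACDEFGHIK"] * 5

    def test_no_window_long_enough_rejected(self):
        proteome = [SeqRecord(Seq("ACDEFGHIK"), id="p1")]
        with pytest.raises(ValueError):
            sample_decoys(proteome, length=10, n_decoys=5, seed=0)

    def test_nonstandard_sequences_are_skipped(self):
        proteome = [
            SeqRecord(Seq("ACDEFGHIKX"), id="bad"),  # X residue: skipped
            SeqRecord(Seq("MMMMMMMMM"), id="good"),
        ]
        decoys = sample_decoys(proteome, length=9, n_decoys=3, seed=1)
        assert decoys == ["MMMMMMMMM"] * 3

    def test_same_seed_reproduces_and_decoys_are_substrings(self):
        proteome = gen_proteome(3000, seed=4)
        a = sample_decoys(proteome, 9, 200, seed=7)
        b = sample_decoys(proteome, 9, 200, seed=7)
        assert a == b
        full = "".join(str(r.seq) for r in proteome)
        concat = {str(r.seq) for r in proteome}
        assert all(len(d) == 9 for d in a)
        assert all(any(d in s for s in concat) for d in a)

    def test_decoy_fasta_cache_records_seed_and_roundtrips(self, tmp_path):
        from Bio import SeqIO

        from phla_audit.evaluation import write_decoys_fasta

        proteome = gen_proteome(2000, seed=4)
        decoys = {9: sample_decoys(proteome, 9, 20, seed=5)}
        path = tmp_path / "decoys.fasta"
        write_decoys_fasta(decoys, path, seed=5)
        records = list(SeqIO.parse(str(path), "fasta"))
        assert [str(r.seq) for r in records] == decoys[9]
        assert all("seed=5" in r.description for r in records)

    def test_per_length_sets_cover_requested_lengths(self):
        proteome = gen_proteome(2000, seed=4)
        decoys = decoys_per_length(proteome, lengths=(8, 11), n_decoys=10, seed=0)
        assert set(decoys) == {8, 11}
        assert {len(d) for d in decoys[11]} == {11}


class TestPPV:
    def test_perfect_separation_gives_one(self):
        assert ppv_from_scores(np.arange(1000, 1010), np.arange(990)) == 1.0

    def test_anti_separation_gives_zero(self):
        assert ppv_from_scores(np.arange(10), np.arange(100, 1090)) == 0.0

    def test_ties_resolve_against_binders(self):
        assert ppv_from_scores(np.ones(5), np.ones(5)) == 0.0

    def test_partial_ordering(self):
        # 2 binders above all decoys, 1 below: top-3 holds 2 binders + 1 decoy
        ppv = ppv_from_scores(np.array([10.0, 9.0, -5.0]), np.array([1.0, 2.0, 3.0]))
        assert ppv == pytest.approx(2 / 3)

    def test_invariant_under_monotone_transform(self, rng):
        binders = rng.normal(1.0, 1.0, size=20)
        decoys = rng.normal(size=200)
        base = ppv_from_scores(binders, decoys)
        assert ppv_from_scores(np.exp(binders), np.exp(decoys)) == base
        assert foop_from_scores(3 * binders + 2, 3 * decoys + 2) == foop_from_scores(
            binders, decoys
        )

    def test_mean_ppv_of_exchangeable_scores_near_prevalence(self, rng):
        # scores i.i.d. -> expected PPV ~= n_a / (n_a + D); small pilot version
        vals = [
            ppv_from_scores(rng.uniform(size=10), rng.uniform(size=190))
            for _ in range(800)
        ]
        expected = 10 / 200
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) <= 4 * se

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ppv_from_scores(np.array([]), np.ones(3))
        with pytest.raises(ValueError):
            foop_from_scores(np.ones(3), np.array([]))


class TestFOOP:
    def test_binder_above_all_decoys_counts(self):
        # rank 0% <= 0.1% threshold
        assert foop_from_scores(np.array([2000.0]), np.arange(1000.0)) == 1.0

    def test_rank_threshold_boundary(self):
        # 1 decoy >= binder out of 1000 -> rank 0.1%, counted;
        # 2 of 1000 -> 0.2%, not counted
        decoys = np.arange(1000.0)
        assert foop_from_scores(np.array([998.5]), decoys) == 1.0
        assert foop_from_scores(np.array([997.5]), decoys) == 0.0

    def test_all_binders_stronger_gives_one(self):
        assert foop_from_scores(np.full(7, 1e6), np.zeros(100)) == 1.0


class TestPerAlleleWrappers:
    def test_wrappers_agree_with_score_functions(self):
        binders = ["PEPA", "PEPC"]
        decoys = ["DECA", "DECC"]
        strengths = {
            ("PEPA", "A*01:01"): 5.0,
            ("PEPC", "A*01:01"): 4.0,
            ("DECA", "A*01:01"): 1.0,
            ("DECC", "A*01:01"): 0.5,
        }
        pred = ScoreTablePredictor(strengths)
        assert ppv_per_allele(binders, decoys, pred, "A*01:01") == 1.0
        assert foop_per_allele(binders, decoys, pred, "A*01:01") == 1.0

    def test_evaluate_predictor_one_row_per_allele_and_monotone_in_separation(self):
        rng = np.random.default_rng(11)
        alleles = ["A*01:01", "B*07:02", "C*04:01"]
        records = [
            PHLARecord("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9)), (a,))
            for a in alleles
            for _ in range(15)
        ]
        ds = PHLADataset(records)
        proteome = gen_proteome(5000, seed=2)
        decoys = decoys_per_length(proteome, lengths=(9,), n_decoys=500, seed=3)
        binders = {(r.peptide, r.alleles[0]) for r in records}

        ppv_by_sep = []
        for sep in (0.0, 2.0, 6.0):
            pred = MockPredictor(
                separation={a: sep for a in alleles}, binders=binders, seed=9
            )
            frame = evaluate_predictor(ds, pred, decoys)
            assert list(frame["allele"]) == sorted(alleles)
            assert ((frame["ppv"] >= 0) & (frame["ppv"] <= 1)).all()
            assert ((frame["foop"] >= 0) & (frame["foop"] <= 1)).all()
            ppv_by_sep.append(frame["ppv"].mean())
        assert ppv_by_sep[0] <= ppv_by_sep[1] <= ppv_by_sep[2]
        assert ppv_by_sep[2] > 0.9


class TestMockPredictor:
    def test_deterministic_and_rank_consistent(self):
        pred = MockPredictor(seed=3)
        s1, r1 = pred.predict("PEPTIDE", "A*01:01")
        s2, r2 = pred.predict("PEPTIDE", "A*01:01")
        assert (s1, r1) == (s2, r2)
        s3, r3 = pred.predict("OTHERPEP", "A*01:01")
        # rank strictly decreases as strength increases
        assert (s1 - s3) * (r3 - r1) >= 0

    def test_unknown_allele_treated_as_zero_separation(self):
        pred = MockPredictor(separation={"A*01:01": 5.0}, binders={("PEP", "B*07:02")})
        s_binder, _ = pred.predict("PEP", "B*07:02")
        s_plain = pred.predict("PEP", "B*07:02")[0]
        assert s_binder == s_plain  # no separation configured for B*07:02
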