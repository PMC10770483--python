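"""Per-allele predictor evaluation: deconvolution, decoys, PPV and FOOP.

A predictor adapter is anything exposing ``predict(peptide, allele) ->
(strength, percentile_rank)`` with strength increasing and percentile rank
decreasing in binding. Multi-allelic MS records are deconvoluted by assigning
each peptide to its strongest-binding candidate allele (lowest percentile
rank) and discarding peptides whose best rank is >= 0.5% — peptides that the
predictor considers non-binders for every candidate.

Accuracy is measured per allele against proteome decoys:

* PPV_a  — rank the allele's n_a true binders together with the decoys from
           strong to weak and take the fraction of true binders in the top
           n_a (1 when binders outrank every decoy, 0 when none do).
* FOOP_a — fraction of true binders whose percentile rank against the D
           decoys, 100 * (# decoys scored at least as strong) / D, is at or
           below 0.1% — i.e., the binder sits within the first D/1000 decoys
           (500 of the default 500,000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import AMINO_ACIDS, PHLADataset, PHLARecord

logger = logging.getLogger(__name__)

DEFAULT_N_DECOYS = 500_000
DEFAULT_RANK_CUTOFF = 0.5  # percentile rank, percent
DEFAULT_FOOP_THRESHOLD = 0.1  # percentile rank, percent
DECOY_LENGTHS = (8, 9, 10, 11)


@runtime_checkable
class PredictorAdapter(Protocol):
    """Contract for any pHLA scoring function.

    ``predict`` returns (strength, percentile_rank): strength is higher for
    stronger predicted binding; percentile rank is lower for stronger binding
    and expressed in percent, as reported by the common "%rank" predictors.
    Implementations must be deterministic for fixed inputs.
    """

    def predict(self, peptide: str, allele: str) -> tuple[float, float]: ...


class PredictorError(RuntimeError):
    """A predictor adapter failed on a (peptide, allele) query."""


# --------------------------------------------------------------- deconvolution
@dataclass
class DeconvolutionLog:
    """Bookkeeping of a deconvolution pass."""

    n_input: int = 0
    n_kept: int = 0
    n_excluded_rank: int = 0
    failed: list[PHLARecord] = field(default_factory=list)


def deconvolute(
    dataset: PHLADataset,
    predictor: PredictorAdapter,
    rank_cutoff: float = DEFAULT_RANK_CUTOFF,
) -> tuple[PHLADataset, DeconvolutionLog]:
    """Assign each record to its strongest-binding candidate allele.

    The candidate with the lowest percentile rank wins (highest strength
    breaks rank ties). Records whose best rank is >= ``rank_cutoff`` percent
    are excluded as non-binders to every candidate. Records on which the
    predictor raises are flagged in the log, never silently dropped.
    """
    log = DeconvolutionLog(n_input=len(dataset))
    kept: list[PHLARecord] = []
    for record in dataset:
        try:
            scored = [
                (allele, *predictor.predict(record.peptide, allele))
                for allele in record.alleles
            ]
        except Exception:
            logger.warning("predictor failed on peptide %s", record.peptide)
            log.failed.append(record)
            continue
        best_allele, _, best_rank = min(scored, key=lambda t: (t[2], -t[1]))
        if best_rank >= rank_cutoff:
            log.n_excluded_rank += 1
            continue
        kept.append(
            PHLARecord(record.peptide, (best_allele,), record.assay, record.label)
        )
    log.n_kept = len(kept)
    return PHLADataset(kept), log


# --------------------------------------------------------------------- decoys
def sample_decoys(
    proteome: Iterable[SeqRecord] | str,
    length: int,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
) -> list[str]:
    """Random peptides of one length cut from a proteome.

    Samples ``n_decoys`` contiguous substrings of ``length`` residues
    uniformly over all valid (sequence, offset) positions, with replacement.
    Sequences containing non-standard residues are skipped. ``proteome`` may
    be a FASTA path or an iterable of Biopython ``SeqRecord`` objects.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    if isinstance(proteome, str):
        proteome = SeqIO.parse(proteome, "fasta")
    sequences = []
    for rec in proteome:
        s = str(rec.seq).upper()
        if not set(s) <= set(AMINO_ACIDS):
            logger.debug("skipping sequence %s: non-standard residues", rec.id)
            continue
        if len(s) >= length:
            sequences.append(s)
    n_windows = np.array([len(s) - length + 1 for s in sequences], dtype=np.int64)
    if n_windows.sum() == 0:
        raise ValueError(f"proteome has no standard-residue sequence of length >= {length}")
    rng = np.random.default_rng(seed)
    positions = rng.integers(0, n_windows.sum(), size=n_decoys)
    offsets = np.cumsum(np.concatenate([[0], n_windows[:-1]]))
    seq_idx = np.searchsorted(offsets, positions, side="right") - 1
    starts = positions - offsets[seq_idx]
    return [sequences[i][j : j + length] for i, j in zip(seq_idx, starts)]


def decoys_per_length(
    proteome: Iterable[SeqRecord] | str,
    lengths: Iterable[int] = DECOY_LENGTHS,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
) -> dict[int, list[str]]:
    """One decoy set per peptide length, with length-specific derived seeds."""
    if isinstance(proteome, str):
        proteome = list(SeqIO.parse(proteome, "fasta"))
    else:
        proteome = list(proteome)
    return {
        length: sample_decoys(proteome, length, n_decoys, seed=seed + length)
        for length in lengths
    }


def write_decoys_fasta(decoys: dict[int, list[str]], path, seed: int) -> None:
    """Cache decoy sets to FASTA, recording the seed in each header."""
    records = [
        SeqRecord(Seq(pep), id=f"decoy_L{length}_{i}", description=f"seed={seed}")
        for length, peps in decoys.items()
        for i, pep in enumerate(peps)
    ]
    SeqIO.write(records, path, "fasta")


# ------------------------------------------------------------------ PPV / FOOP
def ppv_from_scores(
    binder_strengths: np.ndarray, decoy_strengths: np.ndarray
) -> float:
    """PPV from precomputed strengths: binders among the top n_a of the pool.

    Ties are broken against the binders (a decoy with an equal strength ranks
    ahead), so equal-scoring pools cannot inflate PPV.
    """
    binders = np.asarray(binder_strengths, dtype=float)
    decoys = np.asarray(decoy_strengths, dtype=float)
    if binders.size == 0 or decoys.size == 0:
        raise ValueError("PPV needs at least one binder and one decoy")
    n_a = binders.size
    # a binder makes the top n_a iff fewer than n_a competitors outrank it;
    # competitors: all decoys with strength >= binder (ties favor decoys)
    # and binders with strictly greater strength (stable order among binders).
    order = np.sort(binders)[::-1]
    stronger_decoys = np.searchsorted(np.sort(decoys), order, side="left")
    n_decoys_ge = decoys.size - stronger_decoys  # decoys with strength >= binder
    competitors = n_decoys_ge + np.arange(n_a)  # better-ranked binders
    return float(np.count_nonzero(competitors < n_a) / n_a)


def foop_from_scores(
    binder_strengths: np.ndarray,
    decoy_strengths: np.ndarray,
    threshold: float = DEFAULT_FOOP_THRESHOLD,
) -> float:
    """FOOP from precomputed strengths.

    A binder's percentile rank is 100 * (# decoys scored >= its strength) / D;
    the FOOP is the fraction of binders at or below ``threshold`` percent.
    """
    binders = np.asarray(binder_strengths, dtype=float)
    decoys = np.asarray(decoy_strengths, dtype=float)
    if binders.size == 0 or decoys.size == 0:
        raise ValueError("FOOP needs at least one binder and one decoy")
    sorted_decoys = np.sort(decoys)
    n_ge = decoys.size - np.searchsorted(sorted_decoys, binders, side="left")
    ranks = 100.0 * n_ge / decoys.size
    return float(np.mean(ranks <= threshold))


def _score(predictor: PredictorAdapter, peptides: list[str], allele: str) -> np.ndarray:
    out = np.empty(len(peptides))
    for i, pep in enumerate(peptides):
        try:
            out[i] = predictor.predict(pep, allele)[0]
        except Exception as exc:  # pragma: no cover - adapter contract violation
            raise PredictorError(f"predictor failed on ({pep!r}, {allele!r})") from exc
    return out


def ppv_per_allele(
    binders: list[str],
    decoys: list[str],
    predictor: PredictorAdapter,
    allele: str,
) -> float:
    """Score binders and decoys against one allele and compute PPV."""
    return ppv_from_scores(
        _score(predictor, binders, allele), _score(predictor, decoys, allele)
    )


def foop_per_allele(
    binders: list[str],
    decoys: list[str],
    predictor: PredictorAdapter,
    allele: str,
    threshold: float = DEFAULT_FOOP_THRESHOLD,
) -> float:
    """Score binders and decoys against one allele and compute FOOP."""
    return foop_from_scores(
        _score(predictor, binders, allele),
        _score(predictor, decoys, allele),
        threshold,
    )


def evaluate_predictor(
    dataset: PHLADataset,
    predictor: PredictorAdapter,
    decoys: dict[int, list[str]],
    threshold: float = DEFAULT_FOOP_THRESHOLD,
) -> pd.DataFrame:
    """Per-allele PPV and FOOP over a mono-allelic dataset.

    Decoys of the binder's length are pooled per allele: an allele with
    binders of several lengths competes against the union of the matching
    length-specific decoy sets, mirroring how length-matched decoys are used
    in practice. Returns one row per allele: n_a, PPV, FOOP, threshold.
    """
    rows = []
    for allele, peptides in sorted(dataset.binders_by_allele().items()):
        lengths = sorted({len(p) for p in peptides})
        pool: list[str] = []
        for length in lengths:
            if length not in decoys:
                raise ValueError(f"no decoy set for peptide length {length}")
            pool.extend(decoys[length])
        binder_scores = _score(predictor, peptides, allele)
        decoy_scores = _score(predictor, pool, allele)
        rows.append(
            {
                "allele": allele,
                "n_binders": len(peptides),
                "ppv": ppv_from_scores(binder_scores, decoy_scores),
                "foop": foop_from_scores(binder_scores, decoy_scores, threshold),
                "n_decoys": len(pool),
                "foop_threshold": threshold,
            }
        )
    return pd.DataFrame(rows)


class ScoreTablePredictor:
    """Predictor backed by a precomputed (peptide, allele) -> score table.

    ``ranks`` may be omitted, in which case the percentile rank is derived
    from the strength ordering within the table (ties share the worse rank).
    """

    def __init__(
        self,
        strengths: dict[tuple[str, str], float],
        ranks: dict[tuple[str, str], float] | None = None,
    ):
        self.strengths = dict(strengths)
        if ranks is None:
            values = np.sort(np.array(list(self.strengths.values())))
            ranks = {
                key: 100.0
                * (len(values) - np.searchsorted(values, s, side="left"))
                / len(values)
                for key, s in self.strengths.items()
            }
        self.ranks = dict(ranks)

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        key = (peptide, allele)
        if key not in self.strengths:
            raise PredictorError(f"no score for {key!r}")
        return self.strengths[key], self.ranks[key]


# --------------------------------------------------------------- file adapter
class FilePredictor:
    """Predictor backed by a file/subprocess contract.

    Writes the query pairs as TSV (columns peptide, allele), invokes
    ``command <in.tsv> <out.tsv>`` and reads back a TSV with columns
    peptide, allele, strength, percentile_rank. A built-in mock predictor
    (:class:`phla_audit.simulate.MockPredictor`) implements the same
    in-memory contract for testing.
    """

    def __init__(self, command: list[str], workdir: str = "."):
        self.command = list(command)
        self.workdir = workdir
        self._cache: dict[tuple[str, str], tuple[float, float]] = {}

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        key = (peptide, allele)
        if key not in self._cache:
            self.predict_many([key])
        return self._cache[key]

    def predict_many(self, pairs: list[tuple[str, str]]) -> pd.DataFrame:
        import subprocess
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            inp = Path(tmp) / "queries.tsv"
            out = Path(tmp) / "scores.tsv"
            pd.DataFrame(pairs, columns=["peptide", "allele"]).to_csv(
                inp, sep="\t", index=False
            )
            subprocess.run(
                [*self.command, str(inp), str(out)], check=True, capture_output=True
            )
            scores = pd.read_csv(out, sep="\t")
        required = {"peptide", "allele", "strength", "percentile_rank"}
        if not required <= set(scores.columns):
            raise PredictorError(f"adapter output missing columns {required - set(scores.columns)}")
        for row in scores.itertuples():
            self._cache[(row.peptide, row.allele)] = (
                float(row.strength),
                float(row.percentile_rank),
            )
        return scores
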