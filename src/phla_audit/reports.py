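"""End-to-end audits with provenance: audit-data and audit-model.

An audit config is a plain dict (usually loaded from YAML) with paths to the
inputs and per-stage parameters. Every numeric result in a report is
reproducible from the recorded provenance: input paths, seeds, and a hash of
the canonical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import evaluation
from .audit import audit_coverage, coverage_frame, income_group_stats
from .datasets import PHLADataset, per_allele_counts
from .frequencies import FrequencyTable, clean_frequency_table
from .income import IncomeThresholds
from .nomenclature import CLASS_I_LOCI
from .simulate import MockPredictor

logger = logging.getLogger(__name__)

DEFAULTS = {
    "loci": list(CLASS_I_LOCI),
    "sum_tolerance": 0.05,
    "renormalize": True,
    "duplicate_rule": "largest_sample",
    "rank_cutoff": evaluation.DEFAULT_RANK_CUTOFF,
    "foop_threshold": evaluation.DEFAULT_FOOP_THRESHOLD,
    "n_decoys": evaluation.DEFAULT_N_DECOYS,
    "coverage_quantile": 0.90,
    "interpolate_pc90": False,
}


class AuditError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AuditReport:
    """Machine-readable audit outcome with provenance."""

    kind: str
    provenance: dict
    sections: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {"kind": self.kind, "provenance": self.provenance, **self.sections}
        text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _merged(config: dict) -> dict:
    merged = dict(DEFAULTS)
    merged.update(config)
    return merged


def _require(config: dict, keys: list[str], stage: str) -> None:
    missing = [k for k in keys if k not in config or config[k] is None]
    if missing:
        raise AuditError(f"stage {stage!r}: missing config keys {missing}")


def _load_predictor(config: dict):
    """Predictor from config: a mock spec or an external adapter command."""
    if "predictor_command" in config:
        return evaluation.FilePredictor(config["predictor_command"])
    mock = config.get("mock_predictor", {})
    binders = {tuple(pair) for pair in mock.get("binders", [])}
    if "binders_from_dataset" in mock:
        dataset = PHLADataset.from_csv(mock["binders_from_dataset"])
        binders |= {(r.peptide, r.alleles[0]) for r in dataset}
    return MockPredictor(
        separation=mock.get("separation", {}),
        binders=binders,
        seed=int(mock.get("seed", config.get("seed", 0))),
    )


def _prepare_inputs(config: dict) -> tuple[FrequencyTable, PHLADataset, dict]:
    _require(config, ["frequency_table", "dataset"], "inputs")
    loci = tuple(config["loci"])
    table = FrequencyTable.from_csv(config["frequency_table"])
    table, validation, removed = clean_frequency_table(
        table,
        loci=loci,
        sum_tolerance=config["sum_tolerance"],
        renormalize=config["renormalize"],
        duplicate_rule=config["duplicate_rule"],
    )
    if "income_table" in config:
        income = pd.read_csv(config["income_table"], sep=None, engine="python")
        table = table.annotate_income(
            income, IncomeThresholds(), config.get("country_overrides")
        )
    dataset = PHLADataset.from_csv(config["dataset"])
    if len(dataset) == 0:
        raise AuditError("stage 'inputs': dataset is empty")
    cleaning = {
        "validation": validation.sums,
        "duplicates_removed": int(len(removed)),
        "populations_retained": len(table.populations),
    }
    return table, dataset, cleaning


def _deconvolute_multiallelic(
    dataset: PHLADataset, config: dict
) -> tuple[PHLADataset, dict]:
    """Deconvolute only the multi-allelic records; mono-allelic pass through."""
    if dataset.is_monoallelic:
        return dataset, {}
    multi = PHLADataset([r for r in dataset if r.is_multiallelic])
    mono = [r for r in dataset if not r.is_multiallelic]
    predictor = _load_predictor(config)
    resolved, log = evaluation.deconvolute(
        multi, predictor, rank_cutoff=config["rank_cutoff"]
    )
    out = PHLADataset(mono + resolved.records)
    if len(out) == 0:
        raise AuditError("stage 'deconvolution': no records survive the rank cutoff")
    info = {
        "n_multiallelic": log.n_input,
        "n_kept": log.n_kept,
        "n_excluded_rank": log.n_excluded_rank,
        "n_failed": len(log.failed),
    }
    return out, info


def run_audit_data(config: dict) -> AuditReport:
    """Dataset bias audit: per-allele counts, sPC90 per population, income stats."""
    config = _merged(config)
    table, dataset, cleaning = _prepare_inputs(config)

    dataset, deconv_info = _deconvolute_multiallelic(dataset, config)

    counts = per_allele_counts(dataset)
    results = audit_coverage(
        dataset,
        table,
        q=config["coverage_quantile"],
        interpolate=config["interpolate_pc90"],
        loci=tuple(config["loci"]),
    )
    stats = income_group_stats(results)
    return AuditReport(
        kind="audit-data",
        provenance={
            "config_hash": config_hash(config),
            "inputs": {k: str(config[k]) for k in ("frequency_table", "dataset")},
            "seed": config.get("seed"),
        },
        sections={
            "cleaning": cleaning,
            "deconvolution": deconv_info,
            "per_allele_counts": counts,
            "dataset_size": len(dataset.unique_pairs()),
            "coverage": coverage_frame(results),
            "income_stats": stats.to_dict(),
        },
    )


def allele_income_annotation(table: FrequencyTable) -> pd.DataFrame:
    """Income level of the population expressing each allele the most."""
    frame = table.frame
    idx = frame.groupby("allele")["frequency"].idxmax()
    top = frame.loc[idx, ["allele", "population", "income_level", "frequency"]]
    return top.rename(
        columns={
            "population": "top_population",
            "income_level": "top_income_level",
            "frequency": "top_frequency",
        }
    ).reset_index(drop=True)


def run_audit_model(config: dict) -> AuditReport:
    """Predictor bias audit: per-allele PPV and FOOP against proteome decoys."""
    config = _merged(config)
    _require(config, ["dataset", "proteome"], "audit-model")
    dataset = PHLADataset.from_csv(config["dataset"])
    if len(dataset) == 0:
        raise AuditError("stage 'inputs': dataset is empty")
    predictor = _load_predictor(config)
    dataset, _ = _deconvolute_multiallelic(dataset, config)

    proteome = list(SeqIO.parse(config["proteome"], "fasta"))
    decoys = evaluation.decoys_per_length(
        proteome,
        lengths=dataset.peptide_lengths(),
        n_decoys=int(config["n_decoys"]),
        seed=int(config.get("seed", 0)),
    )
    eval_frame = evaluation.evaluate_predictor(
        dataset, predictor, decoys, threshold=config["foop_threshold"]
    )

    # annotate alleles with the income level of the population expressing them most
    if "frequency_table" in config:
        table = FrequencyTable.from_csv(config["frequency_table"])
        table, _, _ = clean_frequency_table(
            table,
            loci=tuple(config["loci"]),
            sum_tolerance=config["sum_tolerance"],
            renormalize=config["renormalize"],
            duplicate_rule=config["duplicate_rule"],
        )
        if "income_table" in config:
            income = pd.read_csv(config["income_table"], sep=None, engine="python")
            table = table.annotate_income(
                income, IncomeThresholds(), config.get("country_overrides")
            )
            annotation = allele_income_annotation(table)
            eval_frame = eval_frame.merge(annotation, on="allele", how="left")

    return AuditReport(
        kind="audit-model",
        provenance={
            "config_hash": config_hash(config),
            "inputs": {k: str(config[k]) for k in ("dataset", "proteome")},
            "seed": config.get("seed"),
        },
        sections={
            "evaluation": eval_frame,
            "n_decoys": int(config["n_decoys"]),
            "rank_cutoff": config["rank_cutoff"],
            "foop_threshold": config["foop_threshold"],
        },
    )
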