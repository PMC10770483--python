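"""Figure export for audit reports (matplotlib, headless backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .income import INCOME_LEVELS


def plot_spc90_by_income(groups: dict[str, list[float]], path) -> None:
    """Boxplot of sPC90 by income level, poorest to richest."""
    ordered = [level for level in INCOME_LEVELS if level in groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([groups[level] for level in ordered], tick_labels=ordered)
    ax.set_xlabel("income level of the population's country")
    ax.set_ylabel("sPC90")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_allele_counts(counts: pd.Series, path, top: int = 50) -> None:
    """Long-tail bar plot of per-allele data-point counts."""
    head = counts.head(top)
    fig, ax = plt.subplots(figsize=(max(6, 0.18 * len(head)), 4))
    ax.bar(range(len(head)), head.to_numpy())
    ax.set_xticks(range(len(head)))
    ax.set_xticklabels(head.index, rotation=90, fontsize=6)
    ax.set_ylabel("data points")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_per_allele_metrics(eval_frame: pd.DataFrame, path) -> None:
    """Per-allele PPV and FOOP scatter, alleles on the x axis."""
    fig, axes = plt.subplots(2, 1, figsize=(max(6, 0.18 * len(eval_frame)), 6), sharex=True)
    x = range(len(eval_frame))
    axes[0].scatter(x, eval_frame["ppv"])
    axes[0].set_ylabel("PPV")
    axes[1].scatter(x, eval_frame["foop"])
    axes[1].set_ylabel("FOOP")
    axes[1].set_xticks(list(x))
    axes[1].set_xticklabels(eval_frame["allele"], rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
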