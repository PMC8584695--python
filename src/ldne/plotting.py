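"""Optional matplotlib renderings of the tabular outputs.

Every figure has an exact tabular twin written by the pipeline; these helpers
only draw those tables.  matplotlib is imported lazily so the core package
works without it.
"""

from __future__ import annotations

import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_ld_decay(genome_bins: pd.DataFrame, path: str) -> None:
    """Mean r² per distance bin (the binned-decay table)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(genome_bins["bin"], genome_bins["mean_r2"], marker="o")
    ax.set_xlabel("pairwise distance")
    ax.set_ylabel("mean $r^2$")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_maf_spectrum(per_chromosome: pd.DataFrame, path: str) -> None:
    """Per-chromosome proportion of SNPs in each MAF category."""
    plt = _plt()
    wide = per_chromosome.pivot(index="chromosome", columns="bin", values="proportion")
    fig, ax = plt.subplots(figsize=(8, 4))
    wide.plot(kind="bar", stacked=True, ax=ax, width=0.85)
    ax.set_ylabel("proportion of SNPs")
    ax.legend(title="MAF", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ne_trajectory(trajectory: pd.DataFrame, path: str) -> None:
    """Ne against generations ago."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trajectory["generations_ago"], trajectory["ne"], marker="o")
    ax.set_xlabel("generations ago")
    ax.set_ylabel("$N_e$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
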