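"""Minor allele frequency computation and the binned MAF spectrum."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeDataset

#: Default spectrum bin edges; categories are half-open (lower, upper].
DEFAULT_MAF_BINS: tuple[float, ...] = (0.02, 0.10, 0.20, 0.30, 0.40, 0.50)


def compute_maf(dataset: GenotypeDataset) -> np.ndarray:
    """Per-marker minor allele frequency, NaN where all genotypes are missing.

    MAF = min(p, 1-p) with p the counted-allele frequency over non-missing
    genotypes; invariant to which allele the dosage counts.
    """
    g = dataset.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


@dataclass
class MafSpectrum:
    """Binned MAF spectrum: per-chromosome and genome-wide bin proportions."""

    bin_edges: tuple[float, ...]
    per_chromosome: pd.DataFrame  # columns: chromosome, bin, n, proportion
    genome_wide: pd.DataFrame  # columns: bin, n, proportion
    mean_maf: float


def maf_spectrum(
    dataset: GenotypeDataset,
    bins: tuple[float, ...] = DEFAULT_MAF_BINS,
) -> MafSpectrum:
    """Bin per-marker MAF into half-open (lower, upper] frequency categories.

    A MAF at a shared boundary (e.g. 0.10) falls in the lower-labelled bin.
    MAF at or below the lowest edge raises: the spectrum is defined on the
    post-QC set, whose MAF filter should already have removed those markers.
    """
    maf = compute_maf(dataset)
    valid = ~np.isnan(maf)
    if (maf[valid] <= bins[0]).any():
        low = float(np.nanmin(maf))
        raise ValueError(
            f"MAF {low:.4f} at or below lowest bin edge {bins[0]}; run QC first"
        )
    labels = [f"({bins[i]:g},{bins[i + 1]:g}]" for i in range(len(bins) - 1)]
    cat = pd.cut(maf[valid], bins=list(bins), labels=labels, right=True)
    chroms = dataset.chromosome_codes()[valid]
    df = pd.DataFrame({"chromosome": chroms, "bin": cat})

    per_chrom = (
        df.groupby(["chromosome", "bin"], observed=False)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = per_chrom.groupby("chromosome")["n"].transform("sum")
    per_chrom["proportion"] = per_chrom["n"] / totals

    gw = df.groupby("bin", observed=False).size().rename("n").reset_index()
    gw["proportion"] = gw["n"] / gw["n"].sum()

    return MafSpectrum(
        bin_edges=tuple(bins),
        per_chromosome=per_chrom,
        genome_wide=gw,
        mean_maf=float(np.nanmean(maf)),
    )
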