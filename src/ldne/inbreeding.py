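"""Method-of-moments inbreeding coefficient from excess homozygosity.

F_i = (O_i - E_i) / (L_i - E_i), where O_i counts the individual's observed
homozygous loci, L_i its genotyped loci and E_i the homozygosity expected
under Hardy-Weinberg with the small-sample correction 2p(1-p)·2N/(2N-1)
(N = genotyped individuals at the locus, p the sample allele frequency).
Loci missing in an individual are excluded from that individual's O, E and L;
allele frequencies still use all individuals genotyped at the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeDataset


@dataclass(frozen=True)
class InbreedingRecord:
    individual: str
    O: int  # observed homozygous loci
    E: float  # expected homozygous loci
    L: int  # genotyped loci
    F: float


def expected_homozygous(freqs: np.ndarray, n: np.ndarray | int) -> float:
    """Expected homozygous-locus count over loci with allele freqs ``freqs``.

    ``n`` is the per-locus (or scalar) count of genotyped individuals used for
    the 2N/(2N-1) correction.  Monomorphic loci (p in {0,1}) raise: QC must
    remove them before F is meaningful.
    """
    p = np.asarray(freqs, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic locus in expected-homozygosity input")
    n = np.asarray(n, dtype=float)
    if (n < 2).any():
        raise ValueError("need >= 2 genotyped individuals per locus")
    het = 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
    return float(np.sum(1.0 - het))


def inbreeding_coefficients(
    dataset: GenotypeDataset,
) -> tuple[list[InbreedingRecord], float]:
    """Per-individual F records and the population mean F.

    Individuals with no genotyped loci get ``F = NaN`` and are excluded from
    the mean.
    """
    g = dataset.genotypes
    obs = g != MISSING
    n_per_locus = obs.sum(axis=0)
    alt = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_per_locus > 0, alt / (2.0 * n_per_locus), np.nan)
    poly = (p > 0) & (p < 1) & (n_per_locus >= 2)
    het_exp = np.where(
        poly,
        2.0 * p * (1.0 - p) * (2.0 * n_per_locus / np.maximum(2.0 * n_per_locus - 1.0, 1.0)),
        np.nan,
    )

    records = []
    fs = []
    for i, iid in enumerate(dataset.individuals):
        use = obs[i] & poly
        L = int(use.sum())
        if L == 0:
            records.append(InbreedingRecord(iid, 0, float("nan"), 0, float("nan")))
            continue
        O = int((g[i, use] != 1).sum())
        E = float(np.sum(1.0 - het_exp[use]))
        denom = L - E
        F = (O - E) / denom if denom != 0 else float("nan")
        records.append(InbreedingRecord(iid, O, E, L, F))
        if np.isfinite(F):
            fs.append(F)
    mean_f = float(np.mean(fs)) if fs else float("nan")
    return records, mean_f


def inbreeding_table(records: list[InbreedingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.individual, r.O, r.E, r.L, r.F) for r in records],
        columns=["individual", "O", "E", "L", "F"],
    )
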