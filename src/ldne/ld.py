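"""Pairwise linkage disequilibrium (r²) between unphased SNP genotypes.

The default estimator is the two-locus EM maximum-likelihood haplotype
frequency estimate under random mating (Hill-style): every genotype
combination except the double heterozygote contributes haplotypes
deterministically; the double-het mass is split between coupling (A1B1/A2B2)
and repulsion (A1B2/A2B1) phase by iterating the expected ratio.  r² is then
D²/(pA1 pA2 pB1 pB2) with D = P11·P22 − P12·P21.

A genotype-correlation ("composite") estimator is available for comparison.
Pair enumeration is windowed per chromosome so genome-scale inputs stay
tractable; results equal the brute-force double loop on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maf import compute_maf
from .model import MISSING, GenotypeDataset

#: Distance bin edges (bp) of the standard LD-decay table:
#: 0-10 kb, 10-25 kb, 25-50 kb, 50-100 kb, 100-500 kb, 0.5-1 Mb, 1-5 Mb, 5-10 Mb.
DEFAULT_BIN_EDGES_BP: tuple[int, ...] = (
    0, 10_000, 25_000, 50_000, 100_000, 500_000, 1_000_000, 5_000_000, 10_000_000
)

DEFAULT_WINDOW_BP: int = 10_000_000

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


class LDUndefinedError(ValueError):
    """r² is undefined (monomorphic locus or too few shared genotypes)."""


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (A1B1, A1B2, A2B1, A2B2)."""

    p11: float
    p12: float
    p21: float
    p22: float

    @property
    def pA1(self) -> float:
        return self.p11 + self.p12

    @property
    def pA2(self) -> float:
        return self.p21 + self.p22

    @property
    def pB1(self) -> float:
        return self.p11 + self.p21

    @property
    def pB2(self) -> float:
        return self.p12 + self.p22

    @property
    def D(self) -> float:
        return self.p11 * self.p22 - self.p12 * self.p21


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _pair_counts(g_a: np.ndarray, g_b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype table over individuals non-missing at both loci."""
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    keep = (g_a != MISSING) & (g_b != MISSING)
    tab = np.zeros((3, 3), dtype=np.int64)
    for i, j in zip(g_a[keep], g_b[keep]):
        tab[int(i), int(j)] += 1
    return tab


def _em_batch(
    N11: np.ndarray,
    N12: np.ndarray,
    N21: np.ndarray,
    N22: np.ndarray,
    dh: np.ndarray,
    H: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over many pairs.

    ``N..`` are unambiguous haplotype counts, ``dh`` the double-heterozygote
    individual counts and ``H`` total haplotype counts (2 x individuals).
    """
    x = dh / 2.0  # coupling-phase double-het count, the one free quantity
    p11 = (N11 + x) / H
    p12 = (N12 + dh - x) / H
    p21 = (N21 + dh - x) / H
    p22 = (N22 + x) / H
    for _ in range(_EM_MAX_ITER):
        coup = p11 * p22
        rep = p12 * p21
        denom = coup + rep
        pc = np.where(denom > 0, coup / np.where(denom > 0, denom, 1.0), 0.5)
        x = dh * pc
        q11 = (N11 + x) / H
        q12 = (N12 + dh - x) / H
        q21 = (N21 + dh - x) / H
        q22 = (N22 + x) / H
        delta = np.max(
            np.abs(np.stack([q11 - p11, q12 - p12, q21 - p21, q22 - p22]))
        ) if len(np.atleast_1d(q11)) else 0.0
        p11, p12, p21, p22 = q11, q12, q21, q22
        if delta < _EM_TOL:
            break
    return p11, p12, p21, p22


def _counts_to_hapcounts(
    tab9: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map stacked 3x3 joint genotype counts (..., 3, 3) to EM inputs."""
    n = tab9
    N11 = 2 * n[..., 0, 0] + n[..., 0, 1] + n[..., 1, 0]
    N12 = 2 * n[..., 0, 2] + n[..., 0, 1] + n[..., 1, 2]
    N21 = 2 * n[..., 2, 0] + n[..., 1, 0] + n[..., 2, 1]
    N22 = 2 * n[..., 2, 2] + n[..., 2, 1] + n[..., 1, 2]
    dh = n[..., 1, 1]
    H = 2.0 * n.sum(axis=(-2, -1))
    return N11, N12, N21, N22, dh, H


def em_haplotype_freqs(g_a: np.ndarray, g_b: np.ndarray) -> HaplotypeFreqs:
    """ML two-locus haplotype frequencies from two unphased dosage vectors.

    Raises :class:`LDUndefinedError` if fewer than two individuals are
    genotyped at both loci or either locus is monomorphic among them.
    """
    tab = _pair_counts(g_a, g_b)
    n_used = int(tab.sum())
    if n_used < 2:
        raise LDUndefinedError(f"only {n_used} individuals non-missing at both loci")
    pA2 = (tab.sum(axis=1) @ np.array([0, 1, 2])) / (2.0 * n_used)
    pB2 = (tab.sum(axis=0) @ np.array([0, 1, 2])) / (2.0 * n_used)
    if pA2 in (0.0, 1.0) or pB2 in (0.0, 1.0):
        raise LDUndefinedError("monomorphic locus among shared genotypes")
    N11, N12, N21, N22, dh, H = _counts_to_hapcounts(tab[None, ...].astype(float))
    p11, p12, p21, p22 = _em_batch(N11, N12, N21, N22, dh.astype(float), H)
    return HaplotypeFreqs(float(p11[0]), float(p12[0]), float(p21[0]), float(p22[0]))


def r2_from_haplofreqs(h: HaplotypeFreqs) -> float:
    """r² = D² / (pA1 pA2 pB1 pB2), clipped to [0, 1] against rounding."""
    denom = h.pA1 * h.pA2 * h.pB1 * h.pB2
    if denom <= 0:
        raise LDUndefinedError("zero allele frequency: r² undefined")
    return float(np.clip(h.D**2 / denom, 0.0, 1.0))


def composite_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Squared Pearson correlation of the two dosage vectors (composite LD)."""
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    keep = (g_a != MISSING) & (g_b != MISSING)
    a, b = g_a[keep], g_b[keep]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        raise LDUndefinedError("undefined composite r²")
    r = np.corrcoef(a, b)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


# ---------------------------------------------------------------------------
# genome-scale pair enumeration
# ---------------------------------------------------------------------------

def pairwise_ld(
    dataset: GenotypeDataset,
    window_bp: int = DEFAULT_WINDOW_BP,
    method: str = "em",
    block_size: int = 512,
) -> pd.DataFrame:
    """r² for every same-chromosome marker pair with 0 < distance <= window.

    Returns a DataFrame with one row per pair (i < j): chromosome, marker ids
    and bp positions, distance_bp, r2 and n_used.  Pairs with undefined r²
    (monomorphic locus in the shared-genotype subset, co-located markers,
    <2 shared genotypes) are skipped; the skip count is in ``.attrs["n_skipped"]``.
    """
    if method not in ("em", "composite"):
        raise ValueError(f"unknown LD method {method!r}")
    pos_all = dataset.positions()
    chrom_all = dataset.chromosome_codes()
    ids = dataset.marker_ids()
    g = dataset.genotypes
    out: list[pd.DataFrame] = []
    n_skipped = 0

    for c in dataset.chromosomes:
        cols = np.nonzero(chrom_all == c)[0]
        m = len(cols)
        if m < 2:
            continue
        pos = pos_all[cols]
        gc = g[:, cols]
        I = [(gc == k).astype(np.float32) for k in range(3)]
        # exclusive upper partner index per left marker
        j_hi = np.searchsorted(pos, pos + window_bp, side="right")

        s = 0
        while s < m:
            e = min(s + block_size, m)
            f = max(int(j_hi[e - 1]), e)
            width = f - s
            # 9 cross-count matrices for the block
            tab = np.empty((e - s, width, 3, 3), dtype=np.float64)
            for a in range(3):
                Ia = I[a][:, s:e]
                for b in range(3):
                    tab[:, :, a, b] = Ia.T @ I[b][:, s:f]
            jj, kk = np.meshgrid(
                np.arange(s, e), np.arange(s, f), indexing="ij"
            )
            sel = (kk > jj) & (kk < j_hi[jj]) & (pos[kk] > pos[jj])
            co_located = (kk > jj) & (kk < j_hi[jj]) & (pos[kk] == pos[jj])
            n_skipped += int(co_located.sum())
            j_idx, k_idx = jj[sel], kk[sel]
            if len(j_idx) == 0:
                s = e
                continue
            t9 = tab[j_idx - s, k_idx - s]
            n_used = t9.sum(axis=(-2, -1))
            pA2 = (t9.sum(axis=-1) @ np.array([0.0, 1.0, 2.0]))
            pB2 = (t9.sum(axis=-2) @ np.array([0.0, 1.0, 2.0]))
            with np.errstate(invalid="ignore", divide="ignore"):
                pA2 = pA2 / (2 * n_used)
                pB2 = pB2 / (2 * n_used)
            ok = (n_used >= 2) & (pA2 > 0) & (pA2 < 1) & (pB2 > 0) & (pB2 < 1)
            n_skipped += int((~ok).sum())
            j_idx, k_idx, t9 = j_idx[ok], k_idx[ok], t9[ok]
            n_used = n_used[ok]
            if len(j_idx):
                if method == "em":
                    N11, N12, N21, N22, dh, H = _counts_to_hapcounts(t9)
                    p11, p12, p21, p22 = _em_batch(N11, N12, N21, N22, dh, H)
                    pA1 = p11 + p12
                    pB1 = p11 + p21
                    D = p11 * p22 - p12 * p21
                    r2 = np.clip(
                        D * D / (pA1 * (1 - pA1) * pB1 * (1 - pB1)), 0.0, 1.0
                    )
                else:
                    r2 = _composite_batch(t9)
                out.append(
                    pd.DataFrame(
                        {
                            "chromosome": c,
                            "snp_a": [ids[cols[j]] for j in j_idx],
                            "snp_b": [ids[cols[k]] for k in k_idx],
                            "bp_a": pos[j_idx],
                            "bp_b": pos[k_idx],
                            "distance_bp": pos[k_idx] - pos[j_idx],
                            "r2": r2,
                            "n_used": n_used.astype(np.int64),
                        }
                    )
                )
            s = e

    if out:
        pairs = pd.concat(out, ignore_index=True)
    else:
        pairs = pd.DataFrame(
            columns=[
                "chromosome", "snp_a", "snp_b", "bp_a", "bp_b",
                "distance_bp", "r2", "n_used",
            ]
        )
    pairs.attrs["n_skipped"] = n_skipped
    pairs.attrs["window_bp"] = window_bp
    pairs.attrs["method"] = method
    return pairs


def _composite_batch(t9: np.ndarray) -> np.ndarray:
    """Squared genotype correlation from stacked 3x3 count tables."""
    n = t9.sum(axis=(-2, -1))
    va = np.arange(3.0)
    sa = t9.sum(axis=-1) @ va
    sb = t9.sum(axis=-2) @ va
    sab = np.einsum("pab,a,b->p", t9, va, va)
    saa = t9.sum(axis=-1) @ va**2
    sbb = t9.sum(axis=-2) @ va**2
    cov = sab / n - (sa / n) * (sb / n)
    var_a = saa / n - (sa / n) ** 2
    var_b = sbb / n - (sb / n) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov * cov / (var_a * var_b)
    return np.clip(r2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# binned decay and sensitivity analyses
# ---------------------------------------------------------------------------

@dataclass
class LDDecay:
    """Binned LD-decay summary: genome-wide and per-chromosome tables."""

    genome: pd.DataFrame  # bin, n_pairs, mean_r2, se_r2
    per_chromosome: pd.DataFrame  # chromosome x bin
    mean_r2_all: float  # mean over every pair regardless of bin
    n_pairs: int
    edges_bp: tuple[int, ...]


def _bin_labels(edges: tuple[int, ...]) -> list[str]:
    def fmt(bp: int) -> str:
        if bp >= 1_000_000 and bp % 1_000_000 == 0:
            return f"{bp // 1_000_000}Mb"
        if bp % 1000 == 0:
            return f"{bp // 1000}kb"
        return f"{bp}bp"

    return [f"{fmt(edges[i])}-{fmt(edges[i + 1])}" for i in range(len(edges) - 1)]


def bin_ld_decay(
    pairs: pd.DataFrame, edges_bp: tuple[int, ...] = DEFAULT_BIN_EDGES_BP
) -> LDDecay:
    """Aggregate pairwise r² into half-open (lower, upper] distance bins.

    A pair at exactly an edge (e.g. 10,000 bp) falls in the lower bin.  Empty
    bins keep n = 0 with NaN mean.
    """
    labels = _bin_labels(edges_bp)
    if len(pairs):
        cat = pd.cut(
            pairs["distance_bp"], bins=list(edges_bp), labels=labels, right=True
        )
        df = pairs.assign(bin=cat)
        gw = (
            df.groupby("bin", observed=False)["r2"]
            .agg(n_pairs="size", mean_r2="mean", sd_r2="std")
            .reset_index()
        )
        gw["se_r2"] = gw["sd_r2"] / np.sqrt(gw["n_pairs"].clip(lower=1))
        per_chrom = (
            df.groupby(["chromosome", "bin"], observed=False)["r2"]
            .agg(n_pairs="size", mean_r2="mean", sd_r2="std")
            .reset_index()
        )
        per_chrom["se_r2"] = per_chrom["sd_r2"] / np.sqrt(
            per_chrom["n_pairs"].clip(lower=1)
        )
        mean_all = float(df["r2"].mean())
        n_pairs = int(len(df))
    else:
        gw = pd.DataFrame(
            {"bin": labels, "n_pairs": 0, "mean_r2": np.nan, "sd_r2": np.nan,
             "se_r2": np.nan}
        )
        per_chrom = gw.iloc[0:0].assign(chromosome=np.nan)
        mean_all, n_pairs = float("nan"), 0
    return LDDecay(
        genome=gw,
        per_chromosome=per_chrom,
        mean_r2_all=mean_all,
        n_pairs=n_pairs,
        edges_bp=tuple(edges_bp),
    )


DEFAULT_MAF_THRESHOLDS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
DEFAULT_SUBSET_SIZES: tuple[int, ...] = (10, 25, 50, 75, 90)


def ld_maf_sensitivity(
    dataset: GenotypeDataset,
    thresholds: tuple[float, ...] = DEFAULT_MAF_THRESHOLDS,
    window_bp: int = DEFAULT_WINDOW_BP,
    edges_bp: tuple[int, ...] = DEFAULT_BIN_EDGES_BP,
) -> pd.DataFrame:
    """LD decay recomputed after filtering markers to MAF > threshold.

    Returns a tidy table keyed by (maf_threshold, bin).
    """
    maf = compute_maf(dataset)
    frames = []
    for thr in thresholds:
        keep = np.nonzero(maf > thr)[0]
        sub = dataset.take_markers(keep)
        decay = bin_ld_decay(pairwise_ld(sub, window_bp=window_bp), edges_bp)
        frames.append(decay.genome.assign(maf_threshold=thr))
    return pd.concat(frames, ignore_index=True)


def ld_sample_size_sensitivity(
    dataset: GenotypeDataset,
    sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES,
    seed: int = 0,
    window_bp: int = DEFAULT_WINDOW_BP,
    edges_bp: tuple[int, ...] = DEFAULT_BIN_EDGES_BP,
) -> pd.DataFrame:
    """LD decay on random without-replacement individual subsets of each size.

    One subset per size, drawn from a generator seeded with ``seed`` so runs
    are bit-identical.  Returns a tidy table keyed by (sample_size, bin).
    """
    rng = np.random.default_rng(seed)
    n = dataset.n_individuals
    frames = []
    for size in sizes:
        if size > n:
            raise ValueError(f"subset size {size} exceeds {n} individuals")
        rows = np.sort(rng.choice(n, size=size, replace=False))
        sub = dataset.take_individuals(rows)
        decay = bin_ld_decay(pairwise_ld(sub, window_bp=window_bp), edges_bp)
        frames.append(decay.genome.assign(sample_size=size))
    return pd.concat(frames, ignore_index=True)


def write_ld_table(pairs: pd.DataFrame, path: str) -> None:
    """Write pairs in the familiar whitespace .ld layout (CHR_A BP_A SNP_A ...)."""
    out = pd.DataFrame(
        {
            "CHR_A": pairs["chromosome"],
            "BP_A": pairs["bp_a"],
            "SNP_A": pairs["snp_a"],
            "CHR_B": pairs["chromosome"],
            "BP_B": pairs["bp_b"],
            "SNP_B": pairs["snp_b"],
            "R2": pairs["r2"],
        }
    )
    out.to_csv(path, sep=" ", index=False)
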