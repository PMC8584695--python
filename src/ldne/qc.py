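"""SNP quality control and per-chromosome marker summaries.

Filters mirror a standard array-QC recipe: keep autosomal markers with call
rate >= 95%, Hardy-Weinberg exact-test p >= 1e-5 and MAF >= 0.02.  The filter
order (autosome -> call rate -> HWE -> MAF) is fixed and reported, so a marker
failing several thresholds is counted once, under the earliest filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maf import compute_maf
from .model import MISSING, GenotypeDataset, is_autosome

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds for marker-level quality control.

    min_call_rate : keep markers genotyped in at least this fraction of
        individuals (default 0.95).
    min_maf : minimum minor allele frequency (default 0.02).
    hwe_p_threshold : remove markers with HWE exact p below this (default 1e-5).
    autosomes_only : drop markers outside chromosomes 1-29 (default True).
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.02
    hwe_p_threshold: float = 1e-5
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)
    config: QCConfig | None = None
    summary: pd.DataFrame | None = None
    empty_result: bool = False

    def __post_init__(self) -> None:
        if self.removed and self.n_input != self.n_retained + sum(self.removed.values()):
            raise ValueError("removal counts do not add up to input marker count")


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg exact test p-value for one biallelic marker.

    Sums, over all heterozygote counts compatible with the observed allele
    counts (same parity), the probabilities of configurations no more probable
    than the observed one — the standard (non-mid-p) exact test.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no genotyped individuals")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:  # monomorphic: single possible configuration
        return 1.0
    # P(het = h) over h with h ≡ n_rare (mod 2), via the recurrence
    #   P(h+2)/P(h) = hom_r(h) * hom_c(h) * 4 / ((h+2)(h+1)) ... built from mode
    probs = {}
    h_mid = n_rare * (2 * n - n_rare) / (2.0 * n - 1.0)
    h = int(h_mid)
    if (h % 2) != (n_rare % 2):
        h += 1
    h = min(h, n_rare)
    probs[h] = 1.0
    # downward: h -> h-2 (two hets become one rare-hom + one common-hom)
    cur = 1.0
    for hh in range(h, 1, -2):
        hom_r = (n_rare - hh) // 2
        hom_c = n - hh - hom_r
        cur *= hh * (hh - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[hh - 2] = cur
    # upward: h -> h+2
    cur = 1.0
    for hh in range(h, n_rare - 1, 2):
        hom_r = (n_rare - hh) // 2
        hom_c = n - hh - hom_r
        cur *= 4.0 * hom_r * hom_c / ((hh + 2.0) * (hh + 1.0))
        probs[hh + 2] = cur
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1.0 + 1e-12)) / total
    return min(1.0, p)


def _genotype_counts(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (hom-ref, het, hom-alt) counts over non-missing genotypes."""
    g = dataset.genotypes
    return (
        (g == 0).sum(axis=0),
        (g == 1).sum(axis=0),
        (g == 2).sum(axis=0),
    )


def apply_qc(dataset: GenotypeDataset, config: QCConfig | None = None) -> tuple[GenotypeDataset, QCReport]:
    """Filter markers and return (filtered dataset, report).

    Filters run in the fixed order autosome -> call rate -> HWE -> MAF; each
    marker is charged to the first filter it fails.
    """
    config = config or QCConfig()
    n_in = dataset.n_markers
    removed = {"non_autosomal": 0, "call_rate": 0, "hwe": 0, "maf": 0}
    keep = np.ones(n_in, dtype=bool)

    if config.autosomes_only:
        auto = np.array([is_autosome(m.chromosome) for m in dataset.markers])
        removed["non_autosomal"] = int((~auto).sum())
        keep &= auto

    n_ind = dataset.n_individuals
    call = (dataset.genotypes != MISSING).sum(axis=0) / max(n_ind, 1)
    fail_cr = keep & (call < config.min_call_rate)
    removed["call_rate"] = int(fail_cr.sum())
    keep &= ~fail_cr

    if config.hwe_p_threshold > 0.0:
        c0, c1, c2 = _genotype_counts(dataset)
        for j in np.nonzero(keep)[0]:
            tot = int(c0[j] + c1[j] + c2[j])
            if tot == 0:
                continue  # fully missing already caught by call rate (if any)
            if hwe_exact_p(int(c0[j]), int(c1[j]), int(c2[j])) < config.hwe_p_threshold:
                keep[j] = False
                removed["hwe"] += 1

    maf = compute_maf(dataset)
    fail_maf = keep & ~(maf >= config.min_maf)  # NaN (all-missing) fails too
    # fully-missing markers have no MAF; charge them to call rate if that
    # filter is disabled, otherwise they were already removed there
    removed["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    filtered = dataset.take_markers(np.nonzero(keep)[0])
    report = QCReport(
        n_input=n_in,
        n_retained=filtered.n_markers,
        removed=removed,
        config=config,
        empty_result=filtered.n_markers == 0,
    )
    for name, cnt in removed.items():
        logger.info("QC filter %s removed %d markers", name, cnt)
    logger.info("QC retained %d / %d markers", report.n_retained, n_in)
    return filtered, report


def marker_summary(
    dataset: GenotypeDataset,
    chrom_lengths_mb: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-chromosome marker table: length, SNP count, interval stats, mean MAF.

    Mean interval is chromosome length / n SNPs when an assembly length is
    supplied, else the observed span divided by (n - 1).  Interval statistics
    need >= 2 markers; chromosomes with fewer get NaN intervals.
    """
    maf = compute_maf(dataset)
    pos = dataset.positions()
    chroms = dataset.chromosome_codes()
    rows = []
    for c in dataset.chromosomes:
        idx = np.nonzero(chroms == c)[0]
        p = pos[idx]
        n = len(idx)
        length_mb = (
            chrom_lengths_mb.get(c) if chrom_lengths_mb else None
        )
        if n >= 2:
            gaps_mb = np.diff(p) / 1e6
            span_mb = (p[-1] - p[0]) / 1e6
            mean_int = (length_mb / n) if length_mb is not None else span_mb / (n - 1)
            longest, shortest = float(gaps_mb.max()), float(gaps_mb.min())
        else:
            mean_int = longest = shortest = float("nan")
            span_mb = 0.0
        rows.append(
            {
                "chromosome": c,
                "length_mb": length_mb if length_mb is not None else span_mb,
                "n_snps": n,
                "mean_interval_mb": mean_int,
                "longest_interval_mb": longest,
                "shortest_interval_mb": shortest,
                "mean_maf": float(np.nanmean(maf[idx])) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def mean_autosome_length(chrom_lengths_mb: dict[int, float]) -> float:
    """Mean chromosome length (Mb) over the supplied autosome lengths."""
    return float(np.mean(list(chrom_lengths_mb.values())))


def hwe_exact_p_enumerate(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Brute-force HWE exact p via direct combinatorial probabilities.

    Independent enumeration oracle: computes P(het = h | allele counts) from
    log-factorials for every feasible h and sums the tail no more probable
    than the observed configuration.  Intended for small n (<= a few hundred).
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    lg = math.lgamma

    def logp(h: int) -> float:
        hr = (n_rare - h) // 2
        hc = n - h - hr
        return (
            lg(n + 1) - lg(hr + 1) - lg(h + 1) - lg(hc + 1)
            + h * math.log(2.0)
            + lg(n_rare + 1) + lg(2 * n - n_rare + 1) - lg(2 * n + 1)
        )

    hs = [h for h in range(n_rare % 2, n_rare + 1, 2)]
    lps = np.array([logp(h) for h in hs])
    ps = np.exp(lps - lps.max())
    ps /= ps.sum()
    p_obs = ps[hs.index(n_Aa)]
    return float(min(1.0, ps[ps <= p_obs * (1 + 1e-12)].sum()))
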