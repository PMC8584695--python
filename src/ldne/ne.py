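"""LD-based effective population size trajectory (Sved relationship).

Under drift-recombination equilibrium, E[r²] ≈ 1/(α + 4·Ne·c) for loci at
recombination fraction c, plus an upward sample-size inflation.  Inverting,

    N_t = (4 f(c))⁻¹ · (1 / E[r²_adj | c] − α),        t = 1 / (2c)

so LD binned by recombination distance yields a trajectory of Ne estimates at
increasing generations ago: tightly linked pairs reflect ancient Ne, loose
pairs recent Ne.  f maps physical distance to recombination fraction (linear
cM/Mb by default; Haldane and Sved-Feldman map functions available), α is the
mutation correction (1 without mutation, ~2 with), and r²_adj subtracts the
sample-size term (1/(2n) by default for unphased genotype data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_R2_ADJ_FLOOR = 1e-12


@dataclass
class NeConfig:
    """Settings of the Ne-trajectory estimator.

    n_bins : number of distance bins, equally spaced in 1/distance so the
        implied generations are roughly evenly covered (default 25).
    min_distance_bp, max_distance_bp : pair-distance window (default
        1-10 Mb; since t = 1/(2c), a decade of distance maps to a decade of
        generations, ~5-50 at 1 cM/Mb, and including much shorter pairs
        would stretch the trajectory over thousands of generations where a
        short simulated or sampled history carries no signal).
    cm_per_mb : genome-average recombination rate (default 1.0 cM/Mb).
    mapping : distance -> recombination-fraction map: "linear", "haldane" or
        "sved_feldman".
    alpha : mutation correction in the Sved equation (1 = no mutation).
    sample_size_correction : "1/(2n)", "1/n" or "none".
    n : genotyped individuals (for the correction term).
    """

    n: int
    n_bins: int = 25
    min_distance_bp: int = 1_000_000
    max_distance_bp: int = 10_000_000
    cm_per_mb: float = 1.0
    mapping: str = "linear"
    alpha: float = 1.0
    sample_size_correction: str = "1/(2n)"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.max_distance_bp <= max(self.min_distance_bp, 0):
            raise ValueError("distance window must be positive")
        if self.mapping not in ("linear", "haldane", "sved_feldman"):
            raise ValueError(f"unknown mapping {self.mapping!r}")
        if self.sample_size_correction not in ("1/(2n)", "1/n", "none"):
            raise ValueError(
                f"unknown sample_size_correction {self.sample_size_correction!r}"
            )


@dataclass(frozen=True)
class NeEstimate:
    """One trajectory row: Ne at ~t generations ago from one distance bin."""

    generations_ago: int
    ne: float
    mean_distance_bp: float
    mean_r2: float
    sd_r2: float
    n_pairs: int
    c: float
    valid: bool


def distance_to_c(d_bp: float, cm_per_mb: float = 1.0, mapping: str = "linear") -> float:
    """Physical distance (bp) to recombination fraction (Morgans).

    linear: c = d · cM/Mb · 1e-8; haldane: c = (1 − e^{−2d'})/2 with d' the
    linear map distance; sved_feldman: c = d'/(1 + 2d').
    """
    if d_bp <= 0:
        raise ValueError("distance must be positive")
    d_morgans = d_bp * cm_per_mb * 1e-8
    if mapping == "linear":
        return d_morgans
    if mapping == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))
    if mapping == "sved_feldman":
        return d_morgans / (1.0 + 2.0 * d_morgans)
    raise ValueError(f"unknown mapping {mapping!r}")


def adjust_r2(r2: float, n: int, correction: str = "1/(2n)") -> float:
    """Subtract the finite-sample inflation from a mean r².

    Floored at a small positive epsilon (with a warning) when the correction
    exceeds the observed LD.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if correction == "1/(2n)":
        term = 1.0 / (2.0 * n)
    elif correction == "1/n":
        term = 1.0 / n
    elif correction == "none":
        term = 0.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    adj = r2 - term
    if adj <= 0:
        logger.warning(
            "adjusted r² %.3g non-positive after %s correction; floored", adj, correction
        )
        return _R2_ADJ_FLOOR
    return adj


def ne_at_bin(c: float, r2_adj: float, alpha: float = 1.0) -> tuple[float, bool]:
    """Ne = (4c)⁻¹ (1/r²_adj − α); returns (Ne, valid).

    ``valid`` is False when 1/r²_adj <= α (LD too strong for a finite positive
    estimate under the model).
    """
    if c <= 0:
        raise ValueError("recombination fraction must be positive")
    if r2_adj <= 0:
        raise ValueError("adjusted r² must be positive")
    inv = 1.0 / r2_adj
    ne = (inv - alpha) / (4.0 * c)
    return ne, inv > alpha


def generations_ago(c: float) -> int:
    """t = 1/(2c), rounded to the nearest integer generation."""
    if c <= 0:
        raise ValueError("recombination fraction must be positive")
    return int(round(1.0 / (2.0 * c)))


def estimate_ne_trajectory(pairs: pd.DataFrame, config: NeConfig) -> pd.DataFrame:
    """Ne trajectory from a pairwise-LD table (columns distance_bp, r2).

    Pairs inside the distance window are partitioned into ``n_bins`` bins
    equally spaced in 1/distance; each bin contributes one row with its mean
    distance, mean and SD of raw r², the implied generations ago t = 1/(2c)
    and the Ne estimate from the bin mean.  Rows are sorted by t ascending;
    empty bins are dropped with a warning.
    """
    d = pairs["distance_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    lo = max(config.min_distance_bp, 1)
    sel = (d > config.min_distance_bp) & (d <= config.max_distance_bp)
    d, r2 = d[sel], r2[sel]
    if len(d) == 0:
        raise ValueError("no pairs inside the distance window")
    inv_edges = np.linspace(1.0 / d.max(), 1.0 / max(d.min(), lo), config.n_bins + 1)
    edges = np.sort(1.0 / inv_edges)  # ascending distances, harmonic spacing
    idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, config.n_bins - 1)

    rows = []
    for b in range(config.n_bins):
        mask = idx == b
        n_pairs = int(mask.sum())
        if n_pairs == 0:
            logger.warning("empty Ne distance bin %d dropped", b)
            continue
        mean_d = float(d[mask].mean())
        mean_r2 = float(r2[mask].mean())
        sd_r2 = float(r2[mask].std(ddof=1)) if n_pairs > 1 else 0.0
        c = distance_to_c(mean_d, config.cm_per_mb, config.mapping)
        r2a = adjust_r2(mean_r2, config.n, config.sample_size_correction)
        ne, valid = ne_at_bin(c, r2a, config.alpha)
        rows.append(
            {
                "generations_ago": generations_ago(c),
                "ne": round(ne) if valid and np.isfinite(ne) else float("nan"),
                "ne_raw": ne,
                "mean_distance_bp": mean_d,
                "mean_r2": mean_r2,
                "sd_r2": sd_r2,
                "n_pairs": n_pairs,
                "c": c,
                "valid": valid,
            }
        )
    out = pd.DataFrame(rows).sort_values("generations_ago", ignore_index=True)
    return out


def required_marker_count(genome_size_bp: float, ld_span_bp: float) -> int:
    """Markers needed so adjacent SNPs sit within the useful-LD span.

    Ceiling of genome size / LD span, e.g. 2.87 Gb at one SNP per 50 kb
    (the distance where mean r² still exceeds 0.2) -> 57,400 SNPs.
    """
    if genome_size_bp <= 0 or ld_span_bp <= 0:
        raise ValueError("sizes must be positive")
    return math.ceil(genome_size_bp / ld_span_bp)
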