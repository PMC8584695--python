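"""Forward-in-time Wright-Fisher diploid simulator with recombination.

Generates SNP-array-like genotype datasets with known truth: discrete
generations, random mating with selfing allowed, per-gamete crossover counts
Poisson in the map length, crossover positions uniform along the chromosome.
The per-generation population size follows an arbitrary trajectory, so
declining-Ne histories are exact by construction.  Markers are placed as a
Poisson process at the configured mean spacing; founder haplotypes are drawn
at linkage equilibrium from a configurable founder allele-frequency spectrum,
and LD then accrues purely through drift and finite-population recombination.

Markers monomorphic in the final sample are dropped (mimicking array QC) and
the drop count reported.  A single seeded generator drives every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import MISSING, GenotypeDataset, Marker


def study_trajectory(
    burn_in_generations: int = 200,
    burn_in_ne: int = 180,
    decline_from: int = 245,
    decline_to: int = 96,
    decline_generations: int = 50,
) -> list[int]:
    """Population-size history emulating a declining crossbred herd.

    A constant burn-in epoch (which sets the short-range LD background)
    followed by a linear decline over the most recent generations.  The
    default decline floor equals the default sample size (96): a census
    below the number of individuals drawn from it is impossible, so the
    emulated herd declines to the point where the whole final generation
    is genotyped.
    """
    decline = np.linspace(decline_from, decline_to, decline_generations)
    return [burn_in_ne] * burn_in_generations + [int(round(x)) for x in decline]


@dataclass
class SimConfig:
    """Wright-Fisher simulation settings.

    ne_trajectory : per-generation diploid census sizes, oldest first; the
        founder generation has size ``ne_trajectory[0]``.
    n_sample : individuals sampled (without replacement) from the final
        generation.
    n_chromosomes, chromosome_length_mb : genome layout.
    marker_spacing_kb : mean inter-marker gap; markers are a Poisson process.
    cm_per_mb : recombination rate; map length = length x rate.
    founder_maf_range : uniform component of the founder spectrum.
    low_freq_frac, low_freq_range : low-frequency excess component.
    missing_rate : per-genotype missingness applied to the emitted matrix.
    seed : mandatory; all randomness flows from one generator.
    """

    seed: int
    ne_trajectory: Sequence[int] = field(default_factory=study_trajectory)
    n_sample: int = 96
    n_chromosomes: int = 3
    chromosome_length_mb: float = 100.0
    marker_spacing_kb: float = 57.0
    cm_per_mb: float = 1.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    low_freq_frac: float = 0.3
    low_freq_range: tuple[float, float] = (0.02, 0.2)
    missing_rate: float = 0.01
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if len(self.ne_trajectory) < 1 or min(self.ne_trajectory) < 2:
            raise ValueError("ne_trajectory needs sizes >= 2")
        if self.marker_spacing_kb <= 0 or self.chromosome_length_mb <= 0:
            raise ValueError("spacing and length must be positive")
        if self.n_sample > self.ne_trajectory[-1]:
            raise ValueError(
                f"cannot sample {self.n_sample} from final population of "
                f"{self.ne_trajectory[-1]}"
            )


@dataclass
class SimTruth:
    """Ground truth retained alongside the emitted genotypes."""

    haplotypes: dict[int, np.ndarray]  # chrom -> (2*n_sample, m) post-drop
    positions: dict[int, np.ndarray]  # chrom -> marker bp
    founder_freqs: dict[int, np.ndarray]  # chrom -> founder allele freqs (kept markers)
    realized_sizes: list[int]
    cm_per_mb: float
    n_dropped_monomorphic: int


def _founder_freqs(rng: np.random.Generator, m: int, config: SimConfig) -> np.ndarray:
    low = rng.random(m) < config.low_freq_frac
    p = rng.uniform(*config.founder_maf_range, size=m)
    p[low] = rng.uniform(*config.low_freq_range, size=int(low.sum()))
    # random allele orientation so the counted allele is not always minor
    flip = rng.random(m) < 0.5
    p[flip] = 1.0 - p[flip]
    return p


def _evolve_chromosome(
    rng: np.random.Generator,
    hap: np.ndarray,
    positions_bp: np.ndarray,
    length_bp: float,
    map_length_m: float,
    trajectory: Sequence[int],
) -> np.ndarray:
    """Run the per-generation WF reproduction over one chromosome."""
    m = hap.shape[1]
    for n_next in trajectory[1:]:
        n_prev = hap.shape[0] // 2
        parents = rng.integers(0, n_prev, size=2 * n_next)  # one per gamete
        n_x = rng.poisson(map_length_m, size=2 * n_next)
        start = rng.integers(0, 2, size=2 * n_next).astype(np.uint8)
        new = np.empty((2 * n_next, m), dtype=hap.dtype)
        plain = n_x == 0
        new[plain] = hap[2 * parents[plain] + start[plain]]
        for g in np.nonzero(~plain)[0]:
            cuts_bp = np.sort(rng.uniform(0.0, length_bp, size=n_x[g]))
            # source haplotype per marker: parity of crossovers to the left
            src = (start[g] + np.searchsorted(cuts_bp, positions_bp)) % 2
            pa = 2 * parents[g]
            new[g] = np.where(src == 0, hap[pa], hap[pa + 1])
        hap = new
    return hap


def simulate(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Run the simulation and return (genotypes, truth)."""
    rng = np.random.default_rng(config.seed)
    trajectory = [int(x) for x in config.ne_trajectory]
    n_final = trajectory[-1]
    sample_idx = None

    markers: list[Marker] = []
    geno_cols: list[np.ndarray] = []
    truth_haps: dict[int, np.ndarray] = {}
    truth_pos: dict[int, np.ndarray] = {}
    truth_freqs: dict[int, np.ndarray] = {}
    n_dropped = 0

    length_bp = config.chromosome_length_mb * 1e6
    map_length_m = config.chromosome_length_mb * config.cm_per_mb / 100.0
    mean_gap = config.marker_spacing_kb * 1e3

    for chrom in range(1, config.n_chromosomes + 1):
        n_guess = int(length_bp / mean_gap * 1.5) + 20
        gaps = rng.exponential(mean_gap, size=n_guess)
        pos = np.cumsum(gaps)
        pos = pos[pos < length_bp]
        while len(pos) < 2:  # degenerate short chromosome: force 2 markers
            pos = np.append(pos, rng.uniform(0, length_bp))
        pos = np.unique(np.round(pos).astype(np.int64) + 1)
        m = len(pos)

        freqs = _founder_freqs(rng, m, config)
        hap = (rng.random((2 * trajectory[0], m)) < freqs).astype(np.uint8)
        hap = _evolve_chromosome(rng, hap, pos.astype(float), length_bp,
                                 map_length_m, trajectory)

        if sample_idx is None:
            sample_idx = rng.choice(n_final, size=config.n_sample, replace=False)
            sample_idx.sort()
        rows = np.empty(2 * config.n_sample, dtype=np.intp)
        rows[0::2] = 2 * sample_idx
        rows[1::2] = 2 * sample_idx + 1
        samp = hap[rows]
        geno = (samp[0::2].astype(np.int8) + samp[1::2].astype(np.int8))

        if config.drop_monomorphic:
            poly = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < 2 * config.n_sample)
            n_dropped += int((~poly).sum())
        else:
            poly = np.ones(m, dtype=bool)
        pos_kept = pos[poly]
        truth_haps[chrom] = samp[:, poly].copy()
        truth_pos[chrom] = pos_kept
        truth_freqs[chrom] = freqs[poly]
        geno = geno[:, poly]
        for j, p in enumerate(pos_kept):
            markers.append(Marker(f"snp{chrom}_{j}", chrom, int(p), "A", "B"))
        geno_cols.append(geno)

    genotypes = np.concatenate(geno_cols, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = MISSING

    individuals = [f"ind{i}" for i in range(config.n_sample)]
    dataset = GenotypeDataset(markers, individuals, genotypes)
    truth = SimTruth(
        haplotypes=truth_haps,
        positions=truth_pos,
        founder_freqs=truth_freqs,
        realized_sizes=trajectory,
        cm_per_mb=config.cm_per_mb,
        n_dropped_monomorphic=n_dropped,
    )
    return dataset, truth


def expected_r2_sved(
    ne: float,
    c: float,
    alpha: float = 1.0,
    n: int | None = None,
    correction: str = "1/(2n)",
) -> float:
    """Sved's equilibrium expectation E[r²] = 1/(α + 4·Ne·c) (+ sample term).

    The algebraic inverse of the Ne estimator; with ``n`` given, the
    finite-sample inflation used by ``adjust_r2`` is added back.
    """
    if c <= 0:
        raise ValueError("recombination fraction must be positive")
    val = 1.0 / (alpha + 4.0 * ne * c)
    if n is not None:
        if correction == "1/(2n)":
            val += 1.0 / (2.0 * n)
        elif correction == "1/n":
            val += 1.0 / n
        elif correction != "none":
            raise ValueError(f"unknown correction {correction!r}")
    return val


def phased_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r² from true phased haplotypes (squared correlation of hap indicators)."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic haplotype column")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
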