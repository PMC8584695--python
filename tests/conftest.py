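import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldne.model import GenotypeDataset, Marker
from ldne.simulate import SimConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(genotypes, chrom=None, positions=None, ids=None):
    """Small-dataset builder for hand-written fixtures."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    chrom = chrom if chrom is not None else [1] * m
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    ids = ids if ids is not None else [f"snp{j}" for j in range(m)]
    markers = [
        Marker(ids[j], int(chrom[j]), int(positions[j]), "A", "G") for j in range(m)
    ]
    individuals = [f"ind{i}" for i in range(n)]
    return GenotypeDataset(markers, individuals, g)


def random_dataset(rng, n=10, m=50, missing_rate=0.05, n_chrom=2):
    g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        g[rng.random((n, m)) < missing_rate] = -1
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=m))
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        k = int((chrom == c).sum())
        pos[chrom == c] = np.sort(rng.choice(10_000_000, size=k, replace=False)) + 1
    alleles = ["AC", "AG", "AT", "CG", "CT", "GT"]
    markers = []
    for j in range(m):
        a = alleles[int(rng.integers(len(alleles)))]
        markers.append(Marker(f"m{j}", int(chrom[j]), int(pos[j]), a[0], a[1]))
    return GenotypeDataset(markers, [f"i{i}" for i in range(n)], g)


@pytest.fixture(scope="session")
def study_sim():
    """Default study-like simulation shared across calibration/sanity tests."""
    cfg = SimConfig(seed=11, n_chromosomes=2, chromosome_length_mb=60.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def constant_ne_sim():
    """Constant-Ne Wright-Fisher run used by LD/Ne sanity checks."""
    cfg = SimConfig(
        seed=7,
        ne_trajectory=[100] * 120,
        n_sample=96,
        n_chromosomes=1,
        chromosome_length_mb=40.0,
        marker_spacing_kb=20.0,
        missing_rate=0.0,
    )
    return simulate(cfg)
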