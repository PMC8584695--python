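"""r² estimation: EM haplotype frequencies, pair enumeration, decay binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from ldne.ld import (
    DEFAULT_BIN_EDGES_BP,
    HaplotypeFreqs,
    LDUndefinedError,
    bin_ld_decay,
    composite_r2,
    em_haplotype_freqs,
    ld_maf_sensitivity,
    ld_sample_size_sensitivity,
    pairwise_ld,
    r2_from_haplofreqs,
)
from ldne.maf import compute_maf
from ldne.model import MISSING
from ldne.simulate import phased_r2

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# independent 1-D likelihood oracle
# ---------------------------------------------------------------------------

def grid_em_oracle(g_a, g_b):
    """ML haplotype frequencies by 1-D search over the coupling split.

    The allele-frequency margins are fixed by the genotype counts, so the only
    free quantity is how many double heterozygotes are in coupling phase.
    Maximises the multinomial genotype likelihood by dense grid + bounded
    refinement, independently of the EM iteration.
    """
    g_a, g_b = np.asarray(g_a), np.asarray(g_b)
    keep = (g_a != MISSING) & (g_b != MISSING)
    tab = np.zeros((3, 3))
    for i, j in zip(g_a[keep], g_b[keep]):
        tab[int(i), int(j)] += 1
    n = tab.sum()
    H = 2 * n
    N11 = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    N12 = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    N21 = 2 * tab[2, 0] + tab[1, 0] + tab[2, 1]
    N22 = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    d = tab[1, 1]

    def negloglik(x):
        p11 = (N11 + x) / H
        p12 = (N12 + d - x) / H
        p21 = (N21 + d - x) / H
        p22 = (N22 + x) / H
        probs = np.array(
            [
                [p11**2, 2 * p11 * p12, p12**2],
                [2 * p11 * p21, 2 * (p11 * p22 + p12 * p21), 2 * p12 * p22],
                [p21**2, 2 * p21 * p22, p22**2],
            ]
        )
        with np.errstate(divide="ignore"):
            ll = np.where(tab > 0, tab * np.log(np.where(probs > 0, probs, 1e-300)), 0.0)
        return -ll.sum()

    if d == 0:
        x_best = 0.0
    else:
        xs = np.linspace(0, d, 2001)
        x0 = xs[np.argmin([negloglik(x) for x in xs])]
        lo, hi = max(0.0, x0 - d / 1000), min(d, x0 + d / 1000)
        res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        x_best = float(res.x)
    return np.array([N11 + x_best, N12 + d - x_best, N21 + d - x_best, N22 + x_best]) / H


def hap_tuple(h: HaplotypeFreqs):
    return np.array([h.p11, h.p12, h.p21, h.p22])


class TestEmHaplotypeFreqs:
    def test_no_double_hets_equals_direct_counting(self):
        g_a = np.array([0, 0, 1, 2, 2, 1, 0, 2])
        g_b = np.array([0, 1, 0, 2, 1, 2, 0, 2])  # no (1,1) pair
        assert not ((g_a == 1) & (g_b == 1)).any()
        h = em_haplotype_freqs(g_a, g_b)
        # direct haplotype tally: phase is unambiguous throughout
        tab = {}
        for a, b in zip(g_a, g_b):
            tab[(a, b)] = tab.get((a, b), 0) + 1
        N = np.zeros(4)
        for (a, b), c in tab.items():
            contrib = {
                (0, 0): [2, 0, 0, 0], (0, 1): [1, 1, 0, 0], (0, 2): [0, 2, 0, 0],
                (1, 0): [1, 0, 1, 0], (1, 2): [0, 1, 0, 1], (2, 0): [0, 0, 2, 0],
                (2, 1): [0, 0, 1, 1], (2, 2): [0, 0, 0, 2],
            }[(a, b)]
            N += c * np.array(contrib)
        np.testing.assert_allclose(hap_tuple(h), N / N.sum(), atol=1e-9)

    def test_with_double_hets_matches_grid_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            g_a = rng.integers(0, 3, size=20)
            g_b = np.where(rng.random(20) < 0.5, g_a, rng.integers(0, 3, size=20))
            if len(np.unique(g_a)) < 2 or len(np.unique(g_b)) < 2:
                continue
            if min(g_a.sum(), g_b.sum()) in (0, 40):
                continue
            h = em_haplotype_freqs(g_a, g_b)
            np.testing.assert_allclose(hap_tuple(h), grid_em_oracle(g_a, g_b), atol=1e-6)

    def test_identical_vectors_perfect_coupling(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        h = em_haplotype_freqs(g, g)
        assert h.p12 == pytest.approx(0.0, abs=1e-9)
        assert h.p21 == pytest.approx(0.0, abs=1e-9)
        assert h.p11 == pytest.approx(h.pA1)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(LDUndefinedError):
            em_haplotype_freqs(np.array([0, 0, 0, 0]), np.array([0, 1, 2, 1]))

    def test_insufficient_overlap_rejected(self):
        g_a = np.array([1, MISSING, MISSING])
        g_b = np.array([MISSING, 1, 1])
        with pytest.raises(LDUndefinedError):
            em_haplotype_freqs(g_a, g_b)


class TestR2:
    def test_complete_ld(self):
        assert r2_from_haplofreqs(HaplotypeFreqs(0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # p11 = pA1 * pB1 with pA1=0.6, pB1=0.5
        h = HaplotypeFreqs(0.30, 0.30, 0.20, 0.20)
        assert r2_from_haplofreqs(h) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_and_indicator_correlation(self):
        h = HaplotypeFreqs(0.4, 0.1, 0.1, 0.4)
        assert r2_from_haplofreqs(h) == pytest.approx(0.36)
        # direct correlation of haplotype indicator variables at 10x frequency
        haps = (
            [(0, 0)] * 4 + [(0, 1)] * 1 + [(1, 0)] * 1 + [(1, 1)] * 4
        )
        a = np.array([x for x, _ in haps], dtype=float)
        b = np.array([y for _, y in haps], dtype=float)
        assert np.corrcoef(a, b)[0, 1] ** 2 == pytest.approx(0.36)

    def test_zero_allele_frequency_rejected(self):
        with pytest.raises(LDUndefinedError):
            r2_from_haplofreqs(HaplotypeFreqs(0.5, 0.5, 0.0, 0.0))

    @given(st.data())
    def test_symmetry_and_relabelling_invariance(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        g_a = rng.integers(0, 3, size=30)
        g_b = np.where(rng.random(30) < 0.6, g_a, rng.integers(0, 3, size=30))
        for g in (g_a, g_b):
            if g.min() == g.max():
                return
            if g.sum() in (0, 60):
                return
        r_ab = r2_from_haplofreqs(em_haplotype_freqs(g_a, g_b))
        r_ba = r2_from_haplofreqs(em_haplotype_freqs(g_b, g_a))
        r_flip = r2_from_haplofreqs(em_haplotype_freqs(2 - g_a, g_b))
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        assert r_ab == pytest.approx(r_flip, abs=1e-7)

    def test_em_matches_phased_truth_without_ambiguity(self, constant_ne_sim):
        """On pairs with no double heterozygotes, EM equals phase-known r²."""
        ds, truth = constant_ne_sim
        hap = truth.haplotypes[1]
        g = ds.genotypes
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(400):
            j, k = rng.integers(0, ds.n_markers, size=2)
            if j == k:
                continue
            both_het = (g[:, j] == 1) & (g[:, k] == 1)
            if both_het.any():
                continue
            try:
                r_em = r2_from_haplofreqs(em_haplotype_freqs(g[:, j], g[:, k]))
                r_true = phased_r2(hap[:, j], hap[:, k])
            except (LDUndefinedError, ValueError):
                continue
            assert r_em == pytest.approx(r_true, abs=1e-6)
            checked += 1
        assert checked >= 20


class TestPairwiseLd:
    def test_pair_count_within_window(self):
        ds = make_dataset(
            np.array([[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0], [1, 2, 1, 1]]),
            positions=[1000, 2000, 3000, 4000],
        )
        pairs = pairwise_ld(ds, window_bp=10_000_000)
        assert len(pairs) == 6  # C(4,2)

    def test_cross_chromosome_pairs_excluded(self):
        ds = make_dataset(
            np.array([[0, 1], [1, 2], [2, 0], [1, 1]]),
            chrom=[1, 2],
            positions=[1000, 1000],
        )
        assert len(pairwise_ld(ds)) == 0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(rng, n=30, m=100, missing_rate=0.05, n_chrom=3)
        pairs = pairwise_ld(ds, window_bp=4_000_000, block_size=17)
        # brute force over all pairs
        expected = {}
        pos = ds.positions()
        chrom = ds.chromosome_codes()
        ids = ds.marker_ids()
        for j in range(ds.n_markers):
            for k in range(j + 1, ds.n_markers):
                if chrom[j] != chrom[k]:
                    continue
                dist = abs(int(pos[k]) - int(pos[j]))
                if dist == 0 or dist > 4_000_000:
                    continue
                try:
                    r2 = r2_from_haplofreqs(
                        em_haplotype_freqs(ds.genotypes[:, j], ds.genotypes[:, k])
                    )
                except LDUndefinedError:
                    continue
                expected[frozenset((ids[j], ids[k]))] = r2
        got = {
            frozenset((row.snp_a, row.snp_b)): row.r2 for row in pairs.itertuples()
        }
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-8)

    def test_composite_method_matches_scalar(self):
        rng = np.random.default_rng(12)
        ds = random_dataset(rng, n=25, m=20, missing_rate=0.1, n_chrom=1)
        pairs = pairwise_ld(ds, method="composite")
        for row in pairs.itertuples():
            j = ds.marker_ids().index(row.snp_a)
            k = ds.marker_ids().index(row.snp_b)
            assert row.r2 == pytest.approx(
                composite_r2(ds.genotypes[:, j], ds.genotypes[:, k]), abs=1e-9
            )


class TestBinning:
    def test_edge_pair_in_lower_bin(self):
        pairs = pd.DataFrame(
            {"chromosome": [1], "distance_bp": [10_000], "r2": [0.5]}
        )
        decay = bin_ld_decay(pairs)
        assert decay.genome.loc[0, "n_pairs"] == 1
        assert decay.genome.loc[1, "n_pairs"] == 0

    def test_mean_of_two_pairs(self):
        pairs = pd.DataFrame(
            {"chromosome": [1, 1], "distance_bp": [5000, 8000], "r2": [0.2, 0.4]}
        )
        decay = bin_ld_decay(pairs)
        assert decay.genome.loc[0, "mean_r2"] == pytest.approx(0.3)
        assert decay.mean_r2_all == pytest.approx(0.3)

    def test_empty_bin_reported_absent(self):
        pairs = pd.DataFrame(
            {"chromosome": [1], "distance_bp": [5000], "r2": [0.2]}
        )
        decay = bin_ld_decay(pairs)
        assert np.isnan(decay.genome.loc[3, "mean_r2"])

    def test_simulated_decay_monotone(self, constant_ne_sim):
        """Constant-Ne Wright-Fisher data: mean r² decreases across bins.

        The two shortest bins are expected to tie: LD at c below ~1e-4 has
        not equilibrated within the simulated epoch and their Sved
        expectations differ by less than the sampling noise, so strict
        ordering is asserted from the second bin on.
        """
        ds, _ = constant_ne_sim
        decay = bin_ld_decay(pairwise_ld(ds))
        means = decay.genome["mean_r2"].to_numpy()
        means = means[~np.isnan(means)]
        assert len(means) >= 6
        assert all(np.diff(means[1:]) < 0)
        assert means[0] > means[3]


class TestSensitivity:
    def test_zero_threshold_is_noop(self, study_sim):
        ds, _ = study_sim
        sub = ds.take_markers(np.arange(0, ds.n_markers, 4))
        table = ld_maf_sensitivity(sub, thresholds=(0.0,), window_bp=2_000_000)
        base = bin_ld_decay(pairwise_ld(sub, window_bp=2_000_000)).genome
        np.testing.assert_allclose(
            table["mean_r2"].to_numpy(), base["mean_r2"].to_numpy(), equal_nan=True
        )

    def test_all_markers_above_top_threshold_curves_identical(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, rng.uniform(0.3, 0.5, 40), size=(40, 40))
        ds = make_dataset(g, positions=np.arange(1, 41) * 20_000)
        assert (compute_maf(ds) > 0.2).all()
        table = ld_maf_sensitivity(ds, window_bp=2_000_000)
        wide = table.pivot(index="bin", columns="maf_threshold", values="mean_r2")
        for col in wide.columns[1:]:
            np.testing.assert_allclose(
                wide[col], wide[wide.columns[0]], equal_nan=True
            )

    def test_full_size_subset_identical_and_deterministic(self, study_sim):
        ds, _ = study_sim
        sub = ds.take_markers(np.arange(0, ds.n_markers, 4))
        t1 = ld_sample_size_sensitivity(
            sub, sizes=(sub.n_individuals,), seed=3, window_bp=2_000_000
        )
        base = bin_ld_decay(pairwise_ld(sub, window_bp=2_000_000)).genome
        np.testing.assert_allclose(
            t1["mean_r2"].to_numpy(), base["mean_r2"].to_numpy(), equal_nan=True
        )
        t2 = ld_sample_size_sensitivity(
            sub, sizes=(10, 25), seed=3, window_bp=2_000_000
        )
        t3 = ld_sample_size_sensitivity(
            sub, sizes=(10, 25), seed=3, window_bp=2_000_000
        )
        pd.testing.assert_frame_equal(t2, t3)

    def test_oversized_subset_rejected(self):
        ds = random_dataset(np.random.default_rng(14), n=5, m=10)
        with pytest.raises(ValueError, match="exceeds"):
            ld_sample_size_sensitivity(ds, sizes=(6,), seed=0)
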