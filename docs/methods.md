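# Methods

`ldne` re-implements, as a tested pipeline, the standard SNP-array analysis of
linkage disequilibrium (LD) and LD-based effective population size (Ne) in a
livestock population: marker QC, the minor-allele-frequency (MAF) spectrum,
pairwise r² and its decay with physical distance, MAF- and sample-size
sensitivity of LD, excess-homozygosity inbreeding, a Sved-equation Ne
trajectory, and the marker-density arithmetic used to size genotyping panels.
A forward Wright–Fisher simulator supplies array-like genotype data with
known truth for validation.

## Genotype model and I/O

Genotypes are diploid biallelic dosages (0/1/2 copies of the counted allele,
−1 missing) over markers sorted by (chromosome, bp). PLINK 1 text (PED/MAP)
and binary (BED/BIM/FAM, SNP-major) files are read and written directly per
the published byte-level format. Dosage counts the BIM A1 allele (binary) or
the second allele by file order of appearance (text). The PED format does not
record which allele is counted, so text round-trips are exact up to
per-marker allele relabelling; `harmonize_alleles` restores a reference
orientation, and every downstream statistic (MAF, r², F) is invariant to the
orientation. Positions are 1-based bp; the cM column is read but unused —
physical distance is converted to map distance with a single genome-wide
cM/Mb rate.

## Quality control

Markers are filtered in a fixed, reported order: autosome (chromosomes 1–29)
→ call rate ≥ 0.95 → Hardy–Weinberg exact-test p ≥ 1e-5 → MAF ≥ 0.02. A
marker failing several criteria is charged to the first. The HWE test is the
standard exact test (sum of probabilities of all heterozygote counts, at
fixed allele counts, no more probable than observed; plain p, not mid-p) —
the default behaviour of the commonly used QC tools. Missing genotypes are
excluded from both allele-frequency and HWE counts. Per-chromosome summaries
report SNP count, mean/longest/shortest adjacent intervals and mean MAF; the
mean interval uses an assembly length when supplied (length / n SNPs), else
the observed span / (n − 1).

## LD estimation

r² between unphased genotypes uses maximum-likelihood two-locus haplotype
frequencies under random mating (Hill-style EM): every genotype pair except
the double heterozygote contributes haplotypes deterministically; the double
heterozygotes are split between coupling and repulsion phase by iterating the
expected ratio until the largest frequency change is below 1e-10 (cap 1000
iterations). Then r² = D²/(p_A1 p_A2 p_B1 p_B2) with D = P11·P22 − P12·P21,
clipped to [0,1] against rounding. The allele-frequency margins are fixed by
the genotype counts, so the EM has a single free quantity; tests verify it
against an independent one-dimensional likelihood search and against
phase-known r² on fixtures without double heterozygotes. A composite
(genotype-correlation) estimator is available behind a flag for comparison.

Missing data are handled pairwise (individuals genotyped at both loci).
Pair enumeration is windowed per chromosome (default ≤ 10 Mb, both loci on
the same autosome, distance 0 excluded) and processed in column blocks whose
3×3 joint genotype tables come from indicator-matrix products, so genome
sized inputs are tractable; on small inputs the result equals a brute-force
double loop, which is a test oracle. Decay is summarised in the standard
eight half-open bins (0–10, 10–25, 25–50, 50–100, 100–500 kb, 0.5–1, 1–5,
5–10 Mb]; a pair on an edge falls in the lower bin. Sensitivity analyses
re-run the decay after filtering markers to MAF > {0.05, 0.10, 0.15, 0.20}
and on seeded random individual subsets of sizes {10, 25, 50, 75, 90}.

## Inbreeding

F_i = (O_i − E_i)/(L_i − E_i) per individual: observed homozygous loci
against the Hardy–Weinberg expectation with the small-sample correction
E = Σ [1 − 2p(1−p)·2N/(2N−1)], p the sample allele frequency and N the
genotyped count at the locus (the method-of-moments estimator of the usual
`--het` output). Loci missing in an individual are excluded from its O, E
and L; frequencies still use all genotyped individuals. Under random mating
the estimator centres on 0; excess homozygosity gives F > 0, excess
heterozygosity F < 0.

## Ne trajectory

Under drift–recombination equilibrium E[r²] ≈ 1/(α + 4 Ne c) (Sved), with α
the mutation correction (1 without mutation, ~2 with) and c the
recombination fraction. Inverting on binned data:

    N_t = (4 f(c))⁻¹ (E[r²_adj | c]⁻¹ − α),   t = 1/(2c)

where f maps mean physical distance to c (linear cM/Mb by default; Haldane
and Sved–Feldman map functions available) and r²_adj subtracts the
finite-sample inflation (1/(2n) default; 1/n and none available). Pairs are
binned uniformly in 1/distance so that t is evenly covered; with the default
1–10 Mb window and 1 cM/Mb this spans roughly generations 5–50 in 25 bins.
The window's lower bound matters: t ∝ 1/distance, so admitting very close
pairs would stretch the trajectory over thousands of generations where
neither a simulated nor a realistically sampled history carries signal, and
leave most 1/d-uniform bins empty. Ne is reported rounded to the nearest
integer with full precision retained; a bin with 1/r²_adj ≤ α has no finite
positive solution and is flagged invalid.

Two caveats are documented deliberately. First, the exact convention behind
any published trajectory (map function, α, sample correction) is often not
recoverable; all three are exposed in `NeConfig` and worked examples are
checked at 10% relative tolerance. Second, the Sved form is an approximation:
simulated data track the Hill–Weir expectation E[r²] ≈
(10+ρ)/((2+ρ)(11+ρ)), ρ = 4Nc, which lies below 1/(1+ρ) at large c, so the
inverted Ne at recent generations runs systematically high by roughly
10–20%. The parameter-recovery tests measure exactly this: median relative
error of recent-generation Ne ≈ 23% at Ne = 50 — inside the 25% validation
bound, but a bias users should know about (it is shared by the family of
Sved-inversion tools, not specific to this implementation).

Marker-density arithmetic: the minimum panel size is ⌈genome size / LD
span⌉, where the LD span is the distance at which mean r² still exceeds the
target (e.g. 0.2): a 2.87 Gb genome needs 57,400 SNPs at one per 50 kb and
28,700 at one per 100 kb.

## Wright–Fisher simulator

Discrete generations; each offspring draws two parents uniformly (selfing
allowed) from the current population, whose per-generation census follows an
arbitrary trajectory — declining histories are therefore exact by
construction, which is why a forward simulator was chosen over a coalescent
one. Each transmitted gamete recombines with a Poisson number of crossovers
in the map length at uniform positions. Markers are placed as a Poisson
process at the configured mean spacing (57 kb default), so all inter-marker
distances occur, as on a real array. Founder haplotypes are drawn at linkage
equilibrium from a founder spectrum (70% uniform on (0.05, 0.5) plus a 30%
low-frequency component on (0.02, 0.2), random orientation); LD then accrues
purely through drift. Markers monomorphic in the final sample are dropped,
mimicking array QC, and counted. One seeded generator drives every draw, so
runs are bit-reproducible.

The default configuration emulates a declining crossbred herd at desk scale:
a 200-generation burn-in at census 180 (which sets the short-range LD
background), a linear decline 245 → 96 over the last 50 generations (96 is
the default sample size, and a census cannot be smaller than the sample
drawn from it), two 60 Mb chromosomes at 57 kb mean spacing, 1 cM/Mb, 1%
missingness. Under these settings the sampled data show a genome-wide mean
MAF near 0.25 with roughly a third of SNPs below 0.20, and sub-10 kb mean r²
near 0.45 — the regime of a 96-animal 50K-array crossbred cattle dataset.
What the simulator does not emulate: array ascertainment bias, mutation
during the simulated epoch (α handles it analytically), selection,
migration, overlapping generations, and variation of recombination rate
along the genome. Passing tests therefore validate the estimators'
statistical behaviour under the stated model, not the biology of any
particular breed.

Simulation-based tests use scaled problem sizes chosen to keep sampling
error well below the asserted tolerances: Ne-recovery runs use 50–250
individuals over 2–3 chromosomes × 30 Mb and 10 replicates; the sanity
checks on F use ~5,000 markers × 100 individuals.

## Numerical choices and degenerate inputs

EM tolerance 1e-10 on haplotype frequencies, 1000-iteration cap; the
double-het split starts at ½. r² is clipped to [0,1]. Pairs with fewer than
two shared genotypes or a locus monomorphic among them are skipped and
counted rather than poisoned with NaN. The adjusted r² is floored at 1e-12
with a warning when the sample correction exceeds the observed LD. MAF and
spectrum bins are half-open (lower, upper]; a value on a shared edge belongs
to the lower-labelled bin. Chromosomes with fewer than two markers get NaN
interval statistics. A fully missing marker has NaN MAF and fails any MAF
threshold. QC with all thresholds at zero is the identity.
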