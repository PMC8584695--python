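# Full-pipeline configuration for `ldne run-all`.
# Either point at existing PLINK files:
#   plink_prefix: /path/to/data     # .bed/.bim/.fam or .ped/.map
# or simulate a study-like dataset (shown here).

seed: 11

simulate:
  seed: 11
  n_sample: 96              # genotyped individuals
  n_chromosomes: 2
  chromosome_length_mb: 60.0
  marker_spacing_kb: 57.0   # mean gap; markers are a Poisson process
  cm_per_mb: 1.0
  missing_rate: 0.01
  # ne_trajectory defaults to a 200-generation burn-in at census 180
  # followed by a linear decline 245 -> 96 over 50 generations

qc:
  min_call_rate: 0.95
  min_maf: 0.02
  hwe_p_threshold: 1.0e-5
  autosomes_only: true

ld:
  window_bp: 10000000
  method: em                # or "composite"
  # bin_edges_bp: [0, 10000, 25000, 50000, 100000, 500000, 1000000, 5000000, 10000000]

ne:
  n_bins: 25
  cm_per_mb: 1.0
  mapping: linear           # linear | haldane | sved_feldman
  alpha: 1.0
  sample_size_correction: "1/(2n)"   # "1/(2n)" | "1/n" | "none"
  # distance window defaults to 1-10 Mb (generations ~5-50 at 1 cM/Mb)

density:
  genome_size_bp: 2.87e9
  ld_span_bp: 50000

sensitivity:
  maf: true                 # decay at MAF > 0.05/0.10/0.15/0.20
  sample_size: true
  sizes: [10, 25, 50, 75, 90]
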