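"""Published reference tables for a bovine 50K-array study population.

Bundled worked-example inputs from a published analysis of 96 crossbred
cattle genotyped on a 50K bead chip: per-autosome assembly lengths and
retained-SNP counts, and the LD-based Ne trajectory's per-bin summaries
(mean pairwise distance, mean r², SD of r²).  These let the estimators be
exercised against printed inputs without access to the (undeposited) raw
genotypes.
"""

from __future__ import annotations

import pandas as pd

#: Autosome lengths (Mb) spanned by retained markers, BTA 1-29.
BTA_LENGTHS_MB: dict[int, float] = {
    1: 158.026, 2: 136.662, 3: 121.144, 4: 120.281, 5: 121.079,
    6: 119.014, 7: 112.384, 8: 112.908, 9: 105.464, 10: 104.164,
    11: 107.178, 12: 90.819, 13: 83.863, 14: 83.153, 15: 84.445,
    16: 81.249, 17: 74.887, 18: 65.401, 19: 63.541, 20: 71.595,
    21: 71.098, 22: 61.216, 23: 52.096, 24: 62.102, 25: 42.804,
    26: 51.046, 27: 45.332, 28: 46.183, 29: 51.102,
}

#: Retained SNP count per autosome after QC.
BTA_SNP_COUNTS: dict[int, int] = {
    1: 2798, 2: 2249, 3: 2117, 4: 2031, 5: 1859, 6: 2513, 7: 2170,
    8: 1994, 9: 1754, 10: 1981, 11: 1840, 12: 1347, 13: 1472, 14: 1450,
    15: 1430, 16: 1392, 17: 1320, 18: 1122, 19: 1178, 20: 1398, 21: 1220,
    22: 1042, 23: 981, 24: 1030, 25: 792, 26: 900, 27: 801, 28: 785,
    29: 885,
}

#: Sample size of the study population (genotyped individuals).
STUDY_N_INDIVIDUALS: int = 96

#: Published Ne-trajectory bin summaries: mean pairwise distance (bp),
#: mean r² and SD of r² per distance bin, most recent generation first.
#: Columns mirror the estimator's output (generations ago, reported Ne,
#: distance, r², SD).
NE_TRAJECTORY_BINS: pd.DataFrame = pd.DataFrame(
    [
        (5, 46, 9426855, 0.0567, 0.0758),
        (6, 49, 8342446, 0.0598, 0.0796),
        (7, 53, 7366372, 0.0627, 0.0830),
        (8, 57, 6489771, 0.0654, 0.0865),  # printed twice as "7"; read as 8
        (9, 61, 5709032, 0.0685, 0.0896),
        (10, 67, 5013219, 0.0712, 0.0930),
        (11, 73, 4397475, 0.0742, 0.0966),
        (13, 79, 3855051, 0.0769, 0.0996),
        (15, 86, 3381675, 0.0803, 0.1032),
        (17, 96, 2969308, 0.0821, 0.1055),
        (19, 106, 2612771, 0.0837, 0.1071),
        (21, 116, 2307237, 0.0866, 0.1116),
        (24, 128, 2047260, 0.0880, 0.1125),
        (27, 141, 1828020, 0.0893, 0.1139),
        (30, 154, 1645198, 0.0907, 0.1149),
        (33, 166, 1494458, 0.0922, 0.1179),
        (36, 178, 1372177, 0.0935, 0.1184),
        (39, 188, 1273826, 0.0951, 0.1197),
        (42, 199, 1196571, 0.0956, 0.1215),
        (44, 205, 1136869, 0.0974, 0.1231),
        (46, 217, 1092011, 0.0959, 0.1217),
        (47, 221, 1059183, 0.0971, 0.1225),
        (48, 228, 1036170, 0.0961, 0.1217),
        (49, 223, 1020495, 0.0993, 0.1256),
        (50, 245, 1001866, 0.0930, 0.1141),
    ],
    columns=["generations_ago", "ne_reported", "mean_distance_bp", "mean_r2", "sd_r2"],
)

#: Bovine genome size used in marker-density arithmetic.
BOVINE_GENOME_BP: float = 2.87e9
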