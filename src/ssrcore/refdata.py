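"""Published summary statistics of the *Castanopsis hystrix* germplasm survey.

The raw genotypes behind the survey were never deposited, but its printed
summary tables are themselves inputs: the provenance sample sizes define the
simulated study design, and the per-locus diversity grid, the AMOVA mean
squares and the core-collection parameter values support desk-reproducible
arithmetic cross-checks (column means, variance-component back-calculation,
retention percentages, ratio-to-size rules).

All values are transcribed as printed, including their rounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: provenance sample sizes of the 232-accession collection (17 provenances)
POPULATION_SIZES: tuple[int, ...] = (12, 26, 15, 9, 9, 17, 18, 24, 8, 23, 5, 9, 2, 15, 12, 15, 13)

#: per-locus diversity grid of the 32 SSR loci (Na, Ne, Ho, He, PIC, I, Fst, Nm)
_LOCUS_ROWS = [
    ("SSR01", 11, 7.901, 0.935, 0.862, 0.910, 2.165, 0.056, 4.200),
    ("SSR02", 8, 5.894, 0.945, 0.811, 0.866, 1.867, 0.074, 3.119),
    ("SSR03", 10, 7.128, 0.856, 0.839, 0.915, 2.045, 0.086, 2.661),
    ("SSR04", 15, 10.931, 0.915, 0.894, 0.958, 2.469, 0.068, 3.438),
    ("SSR05", 10, 6.565, 0.882, 0.828, 0.881, 1.984, 0.068, 3.453),
    ("SSR06", 10, 6.928, 0.741, 0.832, 0.903, 2.028, 0.085, 2.684),
    ("SSR07", 10, 6.495, 0.835, 0.822, 0.888, 2.008, 0.073, 3.169),
    ("SSR08", 10, 7.128, 0.833, 0.812, 0.895, 2.018, 0.112, 1.990),
    ("SSR09", 12, 9.013, 0.955, 0.867, 0.936, 2.275, 0.074, 3.119),
    ("SSR10", 8, 3.832, 0.780, 0.704, 0.744, 1.597, 0.094, 2.408),
    ("SSR11", 9, 5.202, 0.736, 0.733, 0.833, 1.756, 0.138, 1.561),
    ("SSR12", 12, 8.983, 0.966, 0.858, 0.940, 2.248, 0.087, 2.621),
    ("SSR13", 10, 6.631, 0.955, 0.824, 0.890, 2.001, 0.085, 2.681),
    ("SSR14", 12, 9.039, 0.917, 0.858, 0.937, 2.227, 0.085, 2.674),
    ("SSR15", 8, 4.148, 0.775, 0.735, 0.769, 1.620, 0.070, 3.325),
    ("SSR16", 10, 7.294, 0.805, 0.840, 0.919, 2.066, 0.089, 2.551),
    ("SSR17", 10, 5.742, 0.873, 0.808, 0.851, 1.924, 0.060, 3.924),
    ("SSR18", 8, 5.380, 0.809, 0.803, 0.842, 1.831, 0.068, 3.420),
    ("SSR19", 10, 6.745, 0.851, 0.825, 0.885, 2.012, 0.079, 2.924),
    ("SSR20", 13, 9.786, 0.850, 0.882, 0.948, 2.350, 0.073, 3.191),
    ("SSR21", 9, 6.158, 0.909, 0.822, 0.877, 1.919, 0.076, 3.051),
    ("SSR22", 12, 8.673, 0.817, 0.854, 0.932, 2.218, 0.090, 2.533),
    ("SSR23", 8, 4.943, 0.793, 0.765, 0.830, 1.740, 0.095, 2.387),
    ("SSR24", 11, 7.346, 0.942, 0.849, 0.916, 2.100, 0.076, 3.055),
    ("SSR25", 12, 8.840, 0.827, 0.863, 0.941, 2.239, 0.083, 2.780),
    ("SSR26", 10, 5.715, 0.893, 0.801, 0.859, 1.922, 0.074, 3.121),
    ("SSR27", 8, 4.519, 0.753, 0.748, 0.805, 1.664, 0.088, 2.591),
    ("SSR28", 13, 8.364, 0.795, 0.841, 0.920, 2.201, 0.079, 2.925),
    ("SSR29", 11, 7.897, 0.990, 0.849, 0.904, 2.145, 0.066, 3.538),
    ("SSR30", 10, 6.848, 0.902, 0.835, 0.889, 2.032, 0.064, 3.632),
    ("SSR31", 11, 7.722, 0.866, 0.841, 0.918, 2.113, 0.086, 2.656),
    ("SSR32", 14, 9.880, 0.847, 0.873, 0.943, 2.345, 0.075, 3.079),
]

LOCUS_DIVERSITY: pd.DataFrame = pd.DataFrame(
    _LOCUS_ROWS, columns=["Locus", "Na", "Ne", "Ho", "He", "PIC", "I", "Fst", "Nm"]
).set_index("Locus")

#: printed Mean row of the per-locus grid
LOCUS_MEAN_ROW = {"Na": 10, "Ne": 7.115, "Ho": 0.861, "He": 0.824,
                  "PIC": 0.889, "I": 2.035, "Fst": 0.081, "Nm": 2.948}

#: printed total allele count over the 32 loci
TOTAL_ALLELES = 335

#: published AMOVA table: mean squares and headline values
AMOVA_PUBLISHED = {
    "df_among": 16,
    "df_within": 215,
    "ss_among": 771.821,
    "ss_within": 6500.756,
    "ms_among": 48.239,
    "ms_within": 30.236,
    "sigma2_among": 1.338,
    "sigma2_within": 30.236,
    "pct_among": 4.0,
    "pct_within": 96.0,
    "phi_pt": 0.042,
}

#: published original-collection means of the six diversity parameters
ORIGINAL_COLLECTION = {"N": 232, "Na": 26.188, "Ne": 11.565, "Ho": 0.863,
                       "He": 0.897, "I": 2.660, "PIC": 0.8890}

#: published molecular core collections (M-strategy Mc1, ratio-search Mc2)
CORE_COLLECTIONS = {
    "Mc1": {"N": 158, "Na": 26.156, "Ne": 11.826, "Ho": 0.863,
            "He": 0.899, "I": 2.687, "PIC": 0.8916},
    "Mc2": {"N": 128, "Na": 23.594, "Ne": 11.483, "Ho": 0.840,
            "He": 0.899, "I": 2.645, "PIC": 0.8909},
}

#: published retention percentages as printed (sample retention, then per parameter)
CORE_RETENTION_PRINTED = {
    "Mc1": {"N": 68.1, "Na": 99.9, "Ne": 102, "Ho": 100, "He": 100, "I": 101, "PIC": 100},
    "Mc2": {"N": 55.2, "Na": 90.1, "Ne": 99.3, "Ho": 97.3, "He": 100, "I": 99.4, "PIC": 100},
}

#: published ratio-search sampling ratios and their printed core sizes
RATIO_SEARCH_SIZES = {
    0.10: 23, 0.15: 35, 0.20: 46, 0.25: 58, 0.30: 70, 0.35: 81,
    0.40: 93, 0.45: 104, 0.50: 116, 0.55: 128, 0.60: 139,
}


def printed_retention(core: str) -> dict[str, float]:
    """Recompute retention percentages from the printed core and original values,
    rounded to the precision at which they were printed."""
    orig = ORIGINAL_COLLECTION
    sub = CORE_COLLECTIONS[core]
    printed = CORE_RETENTION_PRINTED[core]
    out: dict[str, float] = {}
    for key, shown in printed.items():
        pct = 100.0 * sub[key] / orig[key]
        decimals = len(str(shown).split(".")[1]) if "." in str(shown) else 0
        out[key] = float(np.round(pct, decimals))
    return out
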