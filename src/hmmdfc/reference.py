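"""Published group summary statistics used to validate post-processing.

These are the per-state fractional-occupancy and mean-dwell-time summary
rows (group means +- SD, Mann-Whitney U, raw p, FDR q, rank-biserial
effect and Cohen's d) reported for the 100-patient / 100-control migraine
cohort whose analysis this package reimplements.  The raw data behind
them are not public, but the printed columns are mutually redundant:
the effect sizes are functions of U, n and the group moments, and the
q column is the Benjamini-Hochberg adjustment of the p column (m = 11
states).  That redundancy lets the statistical post-processing be checked
exactly against an independent publication — see ``tests`` and
``scripts/acceptance.py``.

States are 1-based as printed.  ``n1 = n2 = 100``.
"""

from __future__ import annotations

import pandas as pd

N_PER_GROUP = 100

_FO_COLUMNS = ["state", "hc_mean", "hc_sd", "pat_mean", "pat_sd", "u",
               "p", "q", "effect", "cohen_d"]

_FO_ROWS = [
    (1, 0.089, 0.049, 0.087, 0.050, 5100.0, 0.8078, 0.8078, -0.0200, -0.05),
    (2, 0.056, 0.025, 0.057, 0.027, 4741.5, 0.5278, 0.5904, 0.0517, 0.05),
    (3, 0.138, 0.061, 0.071, 0.044, 8154.5, 1.26e-14, 1.39e-13, -0.6309,
     -1.26),
    (4, 0.127, 0.048, 0.085, 0.047, 7325.5, 1.32e-08, 2.90e-08, -0.4651,
     -0.89),
    (5, 0.100, 0.048, 0.118, 0.053, 3987.5, 0.0134, 0.0184, 0.2025, 0.35),
    (6, 0.075, 0.041, 0.111, 0.054, 2984.0, 8.35e-07, 1.53e-06, 0.4032,
     0.74),
    (7, 0.051, 0.049, 0.136, 0.159, 2322.0, 5.93e-11, 2.17e-10, 0.5356,
     0.72),
    (8, 0.130, 0.050, 0.097, 0.049, 6770.0, 1.52e-05, 2.39e-05, -0.3540,
     -0.67),
    (9, 0.058, 0.039, 0.110, 0.050, 2051.5, 5.74e-13, 3.15e-12, 0.5897,
     1.16),
    (10, 0.057, 0.025, 0.058, 0.028, 4747.0, 0.5367, 0.5904, 0.0506, 0.06),
    (11, 0.117, 0.050, 0.070, 0.044, 7616.0, 1.61e-10, 4.43e-10, -0.5232,
     -1.01),
]

_MDT_ROWS = [
    (1, 6.87, 4.14, 6.34, 3.14, 5156.5, 0.7030, 0.7030, -0.0313, -0.14),
    (2, 1.00, 0.00, 0.97, 0.17, 5150.0, 0.0827, 0.1138, -0.0300, -0.25),
    (3, 8.05, 3.72, 6.46, 3.52, 6340.0, 0.0011, 0.0023, -0.2680, -0.44),
    (4, 8.38, 3.83, 6.46, 3.01, 6428.5, 0.0005, 0.0018, -0.2857, -0.56),
    (5, 7.05, 3.45, 7.35, 3.58, 4799.0, 0.6240, 0.6865, 0.0402, 0.09),
    (6, 6.25, 3.24, 7.32, 4.86, 4347.0, 0.1107, 0.1353, 0.1306, 0.26),
    (7, 3.84, 1.98, 6.38, 7.27, 3126.0, 4.63e-06, 5.09e-05, 0.3748, 0.48),
    (8, 7.76, 3.39, 6.88, 3.54, 5809.5, 0.0480, 0.0755, -0.1619, -0.25),
    (9, 5.58, 3.17, 7.02, 2.83, 3455.0, 0.0002, 0.0009, 0.3090, 0.48),
    (10, 1.00, 0.00, 0.96, 0.20, 5200.0, 0.0444, 0.0755, -0.0400, -0.29),
    (11, 7.77, 3.45, 6.34, 3.96, 6349.5, 0.0010, 0.0023, -0.2699, -0.38),
]


def fo_table() -> pd.DataFrame:
    """Fractional-occupancy summary rows, one per state."""
    return pd.DataFrame(_FO_ROWS, columns=_FO_COLUMNS)


def mdt_table() -> pd.DataFrame:
    """Mean-dwell-time summary rows (TR units), one per state."""
    return pd.DataFrame(_MDT_ROWS, columns=_FO_COLUMNS)
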