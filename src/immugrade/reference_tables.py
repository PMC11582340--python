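"""Published cross-tabulations from the 346-case rectal-cancer development cohort.

These printed counts (by treatment group: no preoperative radiotherapy
nRT, short-course radiotherapy SRT, long-course chemoradiotherapy CRT)
serve as worked-example inputs: recomputing their chi-square statistics
and column percentages checks the contingency machinery against values
published to three decimals. CCI counts cover the 344 cases with a known
comorbidity index.
"""

from __future__ import annotations

import numpy as np

TREATMENT_COLUMNS = ("nRT", "SRT", "CRT")
TREATMENT_N = {"nRT": 154, "SRT": 95, "CRT": 97}
COHORT_N = 346

#: rows male / female
SEX_BY_TREATMENT = np.array([[92, 61, 66], [62, 34, 31]])

#: rows mucinous <50% / >=50%
MUCINOUS_BY_TREATMENT = np.array([[149, 90, 88], [5, 5, 9]])

#: rows CCI 0-2 / 3 / >=4 (two cases with unknown CCI excluded)
CCI_BY_TREATMENT = np.array([[49, 41, 46], [41, 28, 31], [63, 25, 20]])

#: rows density score 0 / 1 / 2
DENSITY_SCORE_BY_TREATMENT = np.array([[26, 50, 23], [93, 43, 50], [35, 2, 24]])

#: rows proximity score 0 / 1 / 2
PROXIMITY_SCORE_BY_TREATMENT = np.array([[26, 37, 22], [92, 52, 59], [36, 6, 16]])

#: rows immune grade 0 / 1 / 2 / 3
IMMUNE_GRADE_BY_TREATMENT = np.array(
    [[11, 21, 19], [51, 35, 46], [61, 35, 30], [31, 4, 2]]
)

#: rows CLR density low / high
CLR_BY_TREATMENT = np.array([[52, 42, 76], [102, 53, 21]])


def column_percent(counts: np.ndarray, row: int, col: int) -> float:
    """Column percentage as printed (count over column total, in percent)."""
    counts = np.asarray(counts)
    return 100.0 * counts[row, col] / counts[:, col].sum()


def overall_percent(counts: np.ndarray, row: int) -> float:
    counts = np.asarray(counts)
    return 100.0 * counts[row, :].sum() / counts.sum()
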