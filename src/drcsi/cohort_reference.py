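"""Published cohort summary tables used as inputs to the tabular analyses.

The patient-level data behind the modeled study are not distributed, but
the study report prints the full 2×2 contingency tables of every
dichotomized covariate against nodal status (n = 23 node-negative vs
n = 34 node-positive), plus group means/SDs of the imaging metrics.
Those printed counts are sufficient inputs for the univariate logistic,
χ², and φ-coefficient stages, and are collected here as data.

Table layout: rows = (reference level, index level), columns =
(CLNM−, CLNM+).  The index level (second row) is the one whose odds
ratio is reported.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CONTINGENCY_TABLES", "GROUP_SUMMARIES", "table_for_logit"]

# covariate -> 2x2 counts [[ref CLNM-, ref CLNM+], [index CLNM-, index CLNM+]]
CONTINGENCY_TABLES: dict[str, np.ndarray] = {
    "sex": np.array([[14, 23], [9, 11]]),  # index: female
    "cT": np.array([[11, 6], [12, 28]]),  # index: T3-4
    "HG": np.array([[18, 21], [5, 13]]),  # index: GII / II-III / III
    "TSR": np.array([[17, 20], [6, 14]]),  # index: stroma-rich
    "PNI": np.array([[14, 10], [9, 24]]),  # index: positive
    "Ki67": np.array([[9, 21], [14, 13]]),  # index: high (30% cutoff)
    "p53": np.array([[9, 12], [14, 22]]),  # index: positive
}

# metric -> {group: (mean, sd)}; fractions in percent, ADC µm²/ms, T2 ms
GROUP_SUMMARIES = {
    "V_A": {"NC": (75.6, 8.0), "CLNM_neg": (47.9, 20.8), "CLNM_pos": (30.3, 14.8)},
    "V_B": {"NC": (1.4, 1.4), "CLNM_neg": (17.4, 11.8), "CLNM_pos": (28.9, 10.9)},
    "V_C": {"NC": (0.1, 0.2), "CLNM_neg": (0.4, 0.5), "CLNM_pos": (0.6, 0.7)},
    "V_D": {"NC": (2.6, 3.5), "CLNM_neg": (16.2, 10.0), "CLNM_pos": (24.6, 10.0)},
    "V_E": {"NC": (20.4, 7.5), "CLNM_neg": (18.0, 10.3), "CLNM_pos": (15.5, 5.5)},
    "ADC": {"NC": (1.47, 0.16), "CLNM_neg": (1.07, 0.17), "CLNM_pos": (0.96, 0.09)},
    "T2": {"NC": (52.6, 11.9), "CLNM_neg": (60.0, 15.0), "CLNM_pos": (61.8, 16.0)},
}

#: reported correlation between V_B and depth of invasion (collinearity input)
VB_DOI_CORRELATION = 0.31


def table_for_logit(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 2×2 covariate table to per-patient (outcome, predictor) arrays.

    The counts fully determine the patient-level coding for a binary
    covariate, so logistic fits on the expansion are exact reproductions.
    """
    t = CONTINGENCY_TABLES[name]
    outcome, predictor = [], []
    for level in (0, 1):
        for clnm in (0, 1):
            outcome.extend([clnm] * int(t[level, clnm]))
            predictor.extend([level] * int(t[level, clnm]))
    return np.array(outcome, dtype=float), np.array(predictor, dtype=float)
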