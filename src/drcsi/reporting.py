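"""Cohort-level result tables: group comparisons and logistic summaries.

Builds the two tables a reader of this kind of study expects: a
characteristics table with the normality-gated test per variable, and a
univariate + backward-selected multivariate logistic table with odds
ratios and Wald 95% intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as st

__all__ = ["CONTINUOUS_VARS", "BINARY_VARS", "group_comparison_table", "logistic_table"]

CONTINUOUS_VARS = ["age", "MD", "DOI", "V_A", "V_B", "V_C", "V_D", "V_E", "ADC", "T2"]
BINARY_VARS = ["sex", "cT", "HG", "TSR", "PNI", "Ki67", "p53"]


def group_comparison_table(df: pd.DataFrame, outcome: str = "CLNM") -> pd.DataFrame:
    """Two-group comparison of every clinical and imaging variable."""
    neg, pos = df[df[outcome] == 0], df[df[outcome] == 1]
    rows = []
    for col in CONTINUOUS_VARS:
        if col not in df:
            continue
        res = st.compare_groups((neg[col], pos[col]), "continuous")
        rows.append(
            {
                "variable": col,
                "test": res.test,
                "group_neg": f"{neg[col].mean():.2f} ± {neg[col].std():.2f}",
                "group_pos": f"{pos[col].mean():.2f} ± {pos[col].std():.2f}",
                "p_value": res.p_value,
            }
        )
    for col in BINARY_VARS:
        if col not in df:
            continue
        table = pd.crosstab(df[col], df[outcome]).reindex(
            index=[0, 1], columns=[0, 1], fill_value=0
        )
        res = st.compare_groups(table.values, "categorical")
        rows.append(
            {
                "variable": col,
                "test": res.test,
                "group_neg": f"{table.loc[1, 0]}/{table[0].sum()}",
                "group_pos": f"{table.loc[1, 1]}/{table[1].sum()}",
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def logistic_table(df: pd.DataFrame, outcome: str = "CLNM") -> pd.DataFrame:
    """Univariate ORs for every candidate plus the backward-selected joint fit."""
    candidates = [c for c in CONTINUOUS_VARS + BINARY_VARS if c in df and df[c].var() > 0]
    rows = []
    for col in candidates:
        t = st.univariate_logistic(df[outcome], df[col], col).terms[0]
        rows.append(
            {
                "analysis": "univariate",
                "variable": col,
                "OR": t.odds_ratio,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p_value": t.p_value,
            }
        )
    out = pd.DataFrame(rows)
    significant = out.loc[out.p_value < 0.05, "variable"].tolist()
    if significant:
        fit, kept = st.backward_selection(df[outcome], df[significant])
        for t in fit.terms:
            out.loc[len(out)] = {
                "analysis": "multivariate",
                "variable": t.name,
                "OR": t.odds_ratio,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p_value": t.p_value,
            }
    return out
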