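"""Cohort-level inference: group comparisons, agreement, correlation,
logistic regression, ROC, nomogram, and calibration.

The analysis chain mirrors standard radiology practice for a two-group
(node-negative vs node-positive) imaging-biomarker study:

1. continuous metrics are compared with a normality-gated two-sample test
   (Shapiro–Wilk at α = 0.05 per group deciding Welch t vs Mann–Whitney U);
   categorical metrics with Pearson χ² (no continuity correction);
2. interobserver agreement with ICC(2,1) — two-way random effects,
   absolute agreement, single measurement — banded poor/fair/good/excellent;
3. associations with Pearson, point-biserial, or phi coefficients by
   variable kind;
4. univariate then multivariate logistic regression with Wald 95% CIs,
   backward elimination at p ≥ 0.05, and VIF collinearity checks;
5. ROC analysis with trapezoidal AUC, DeLong CI, and Youden-index cutoff;
6. a points-based nomogram over the final bivariate model, with a
   bootstrap-corrected calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy.special import expit
from sklearn.metrics import roc_curve

__all__ = [
    "GroupComparison",
    "LogisticTerm",
    "LogisticResult",
    "RocResult",
    "Nomogram",
    "compare_groups",
    "icc_agreement",
    "correlate",
    "phi_coefficient",
    "univariate_logistic",
    "multivariate_logistic",
    "backward_selection",
    "vif",
    "roc_analysis",
    "delong_ci",
    "combined_model",
    "build_nomogram",
    "calibration_curve",
]

Z_95 = 1.959964  # two-sided 95% normal quantile used for all Wald intervals


# ---------------------------------------------------------------------------
# group comparisons and agreement


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float


def compare_groups(groups, kind: str = "continuous") -> GroupComparison:
    """Two-group (or contingency) comparison with the normality gate.

    ``kind='continuous'`` expects two 1-D samples: both Shapiro–Wilk normal
    at α = 0.05 → Welch t-test, otherwise Mann–Whitney U (tie-corrected,
    two-sided).  ``kind='categorical'`` expects a contingency table of
    counts and applies Pearson χ² without continuity correction.
    """
    if kind == "categorical":
        table = np.asarray(groups, dtype=float)
        if np.any(table < 0):
            raise ValueError("contingency counts must be nonnegative")
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return GroupComparison("chi2", float(chi2), float(p))
    if kind != "continuous":
        raise ValueError(f"unknown kind {kind!r}")
    a, b = (np.asarray(g, dtype=float) for g in groups)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    # Shapiro requires non-constant input; constant samples are non-normal
    def _normal(x):
        if np.ptp(x) == 0 or x.size < 3:
            return False
        return sps.shapiro(x).pvalue >= 0.05

    if _normal(a) and _normal(b):
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison("welch_t", float(res.statistic), float(res.pvalue))
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparison("mannwhitney_u", float(a.size * b.size / 2), 1.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mannwhitney_u", float(res.statistic), float(res.pvalue))


_ICC_BANDS = ((0.4, "poor"), (0.6, "fair"), (0.75, "good"))


def icc_agreement(ratings: np.ndarray) -> tuple[float, str]:
    """ICC(2,1) for a (2 raters × n subjects) array, with its band label.

    Bands: poor < 0.4 ≤ fair < 0.6 ≤ good ≤ 0.75 < excellent.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] != 2:
        raise ValueError("ratings must be 2 raters × n subjects")
    n = ratings.shape[1]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("missing ratings are not supported")
    if np.ptp(ratings.mean(axis=0)) == 0 and np.ptp(ratings) == 0:
        return 1.0, icc_band(1.0)
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat([0, 1], n),
            "score": ratings.ravel(),
        }
    )
    res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    # two-way random effects, absolute agreement, single rater
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    icc = float(row["ICC"].iloc[0])
    if not np.isfinite(icc):
        raise ValueError("ICC undefined (no between-subject variance)")
    return icc, icc_band(icc)


def icc_band(icc: float) -> str:
    for cut, label in _ICC_BANDS:
        if icc < cut or (cut == 0.75 and icc <= cut):
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# correlation


def phi_coefficient(table: np.ndarray) -> float:
    """φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)) for a 2×2 count table."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        raise ValueError("phi undefined: a margin is zero")
    return float((a * d - b * c) / denom)


def correlate(x, y, kinds: tuple[str, str] = ("continuous", "continuous")) -> float:
    """Association coefficient chosen by variable kinds.

    continuous–continuous → Pearson ρ; continuous–binary → point-biserial
    (Pearson on {0,1} coding); binary–binary → φ from the 2×2 table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if kinds == ("binary", "binary"):
        table = np.array(
            [
                [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
                [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
            ]
        )
        return phi_coefficient(table)
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flagged: bool = False


@dataclass(frozen=True)
class LogisticResult:
    terms: tuple[LogisticTerm, ...]
    intercept: float
    converged: bool
    llf: float

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(data), self.intercept)
        for t in self.terms:
            eta = eta + t.coef * np.asarray(data[t.name], dtype=float)
        return eta

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> LogisticResult:
    design = sm.add_constant(X.astype(float), has_constant="add")
    flagged = False
    model = sm.Logit(np.asarray(y, dtype=float), design)
    try:
        fit = model.fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, PerfectSeparationError):
        # separation: quasi-complete ML has no finite optimum; a gradient
        # fit still yields a usable (finite, flagged) linear predictor
        fit = model.fit(disp=0, maxiter=500, method="bfgs")
        flagged, converged = True, False
    terms = []
    for name in X.columns:
        coef = float(fit.params[name])
        se = float(fit.bse[name])
        bad = flagged or not converged or not np.isfinite(se) or se > 1e3
        terms.append(
            LogisticTerm(
                name=name,
                coef=coef,
                se=se,
                odds_ratio=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z_95 * se)),
                ci_high=float(np.exp(coef + Z_95 * se)),
                p_value=float(fit.pvalues[name]),
                flagged=bad,
            )
        )
    return LogisticResult(
        tuple(terms), float(fit.params["const"]), converged, float(fit.llf)
    )


def univariate_logistic(outcome, predictor, name: str = "x") -> LogisticResult:
    """Single-predictor ML logistic fit with Wald 95% CI.

    For a binary predictor the fitted odds ratio equals the 2×2
    cross-product ratio exactly (the saturated-model identity).
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = pd.DataFrame({name: np.asarray(predictor, dtype=float)})
    return _fit_logit(y, X)


def multivariate_logistic(outcome, predictors: pd.DataFrame) -> LogisticResult:
    """Joint ML logistic fit over a predictor table, Wald 95% CIs per term."""
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = predictors.copy()
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.values]))
    if rank < X.shape[1] + 1:
        terms = tuple(
            LogisticTerm(c, np.nan, np.inf, np.nan, np.nan, np.nan, np.nan, True)
            for c in X.columns
        )
        return LogisticResult(terms, np.nan, False, np.nan)
    return _fit_logit(y, X)


def backward_selection(
    outcome, candidates: pd.DataFrame, entry_p: float = 0.05, exit_p: float = 0.05
) -> tuple[LogisticResult, list[str]]:
    """Univariate screen (p < entry_p) then backward elimination (p ≥ exit_p).

    Returns the final multivariate fit and the retained variable names.
    """
    entered = [
        c
        for c in candidates.columns
        if univariate_logistic(outcome, candidates[c], c).terms[0].p_value < entry_p
    ]
    if not entered:
        raise ValueError("no predictor passes the univariate screen")
    current = list(entered)
    while len(current) > 1:
        fit = multivariate_logistic(outcome, candidates[current])
        worst = max(fit.terms, key=lambda t: (t.p_value if np.isfinite(t.p_value) else 2))
        if np.isfinite(worst.p_value) and worst.p_value < exit_p:
            break
        current.remove(worst.name)
    return multivariate_logistic(outcome, candidates[current]), current


def vif(predictors: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per predictor: VIF_k = 1/(1 − R²_k).

    R²_k comes from the OLS regression (with intercept) of predictor k on
    the others; perfect collinearity yields an infinite sentinel.
    """
    if predictors.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out: dict[str, float] = {}
    X = predictors.astype(float)
    for col in X.columns:
        if X[col].var() == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = float("inf") if r2 >= 1 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    cutoff: float
    degenerate: bool = False


def _delong_variance(y: np.ndarray, score: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via the placement-value decomposition."""
    pos = score[y == 1]
    neg = score[y == 0]
    m, n = pos.size, neg.size
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def delong_ci(outcome, score, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with its DeLong normal-approximation confidence interval."""
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    auc, var = _delong_variance(y, s)
    half = sps.norm.ppf(1 - alpha / 2) * np.sqrt(var)
    return auc, max(auc - half, 0.0), min(auc + half, 1.0)


def roc_analysis(outcome, score, higher_is_positive: bool = True) -> RocResult:
    """ROC curve with trapezoidal AUC, DeLong CI, and Youden cutoff.

    The trapezoidal AUC over all observed thresholds equals the normalized
    Mann–Whitney U statistic.  The reported cutoff maximizes Youden's
    J = sensitivity + specificity − 1, ties broken toward higher specificity.
    """
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if not higher_is_positive:
        s = -s
    if np.ptp(s) == 0:
        return RocResult(0.5, 0.5, 0.5, 1.0, 0.0, float(s[0]), degenerate=True)
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    _, lo, hi = delong_ci(y, s)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # among Youden ties prefer the lowest false-positive rate
    pick = best[np.argmin(fpr[best])]
    cutoff = float(thresholds[pick])
    if not higher_is_positive:
        cutoff = -cutoff
    return RocResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        sensitivity=float(tpr[pick]),
        specificity=float(1 - fpr[pick]),
        cutoff=cutoff,
    )


def combined_model(outcome, data: pd.DataFrame, variables=("DOI", "V_B")):
    """Bivariate logistic fit whose linear predictor serves as a ROC score."""
    fit = multivariate_logistic(outcome, data[list(variables)])
    score = fit.linear_predictor(data)
    return fit, score, roc_analysis(outcome, score)


# ---------------------------------------------------------------------------
# nomogram and calibration


@dataclass(frozen=True)
class Nomogram:
    """Points-based rendering of a logistic model.

    Each variable's axis runs over its stated range; the variable with the
    largest |coef|·range-width spans 0–100 points and the others scale
    proportionally.  Negative coefficients count points from the range
    maximum downward so that more points always means more risk; the total
    then maps affinely back onto the linear predictor.
    """

    terms: tuple[LogisticTerm, ...]
    ranges: dict[str, tuple[float, float]]
    base_eta: float
    eta_per_point: float

    def points(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for t in self.terms:
            lo, hi = self.ranges[t.name]
            x = np.asarray(data[t.name], dtype=float)
            delta = (x - lo) if t.coef >= 0 else (hi - x)
            cols[t.name] = abs(t.coef) * delta / self.eta_per_point
        pts = pd.DataFrame(cols)
        pts["total"] = pts.sum(axis=1)
        return pts

    def risk_from_points(self, total_points) -> np.ndarray:
        eta = self.base_eta + self.eta_per_point * np.asarray(total_points, dtype=float)
        return expit(eta)


def build_nomogram(fit: LogisticResult, ranges: dict[str, tuple[float, float]]) -> Nomogram:
    """Lay out nomogram axes for a fitted model over per-variable ranges."""
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"zero-width range for {name!r}")
    widths = {t.name: abs(t.coef) * (ranges[t.name][1] - ranges[t.name][0]) for t in fit.terms}
    max_width = max(widths.values())
    if max_width <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    base = fit.intercept
    for t in fit.terms:
        lo, hi = ranges[t.name]
        base += t.coef * (lo if t.coef >= 0 else hi)
    return Nomogram(
        terms=fit.terms,
        ranges=dict(ranges),
        base_eta=float(base),
        eta_per_point=float(max_width / 100.0),
    )


def calibration_curve(
    fit: LogisticResult,
    data: pd.DataFrame,
    outcome_col: str = "CLNM",
    bins: int = 10,
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned observed-vs-predicted calibration with bootstrap optimism.

    Predictions are split into quantile bins (empty/degenerate bins merge
    with their neighbor); the corrected curve subtracts the mean bootstrap
    optimism (refit on resample, evaluated on the original data) from the
    apparent observed frequencies.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if bootstrap_reps < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    rng = np.random.default_rng(seed)
    y = np.asarray(data[outcome_col], dtype=float)
    pred = fit.predict_proba(data)
    if np.ptp(pred) < 1e-12:
        return pd.DataFrame(
            {
                "bin": [0],
                "predicted": [float(pred.mean())],
                "observed": [float(y.mean())],
                "corrected": [float(y.mean())],
                "n": [len(y)],
                "degenerate": [True],
            }
        )
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(edges, pred, side="right") - 1, 0, len(edges) - 2)
    names = [t.name for t in fit.terms]
    boot_obs = np.zeros((bootstrap_reps, len(edges) - 1))
    boot_pred = np.zeros_like(boot_obs)
    for r in range(bootstrap_reps):
        take = rng.integers(0, len(y), len(y))
        sample = data.iloc[take]
        try:
            refit = multivariate_logistic(sample[outcome_col], sample[names])
            p_orig = refit.predict_proba(data)
        except ValueError:
            p_orig = pred
        for b in range(len(edges) - 1):
            sel = idx == b
            boot_obs[r, b] = y[sel].mean() if sel.any() else np.nan
            boot_pred[r, b] = p_orig[sel].mean() if sel.any() else np.nan
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        apparent = float(y[sel].mean())
        optimism = float(np.nanmean(boot_pred[:, b] - boot_obs[:, b]))
        rows.append(
            {
                "bin": b,
                "predicted": float(pred[sel].mean()),
                "observed": apparent,
                "corrected": apparent - optimism,
                "n": int(sel.sum()),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
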