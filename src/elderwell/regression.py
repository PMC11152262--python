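"""OLS with heteroskedasticity-robust standard errors for the three
wellbeing indices, and the side-by-side comparison table.

One linear model per index, all sharing the predictor set used by the
trees: the learning-attitude dummy, the two activity counts, and the
demographic/health dummies.  Coefficients come from ordinary least squares;
the covariance is a White sandwich estimator (HC1 by default, the
degrees-of-freedom-adjusted variant most econometrics packages print).
Significance stars follow the usual 1/5/10% convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

PREDICTORS = (
    "learn_elderly",
    "class_total",
    "places_total",
    "disability",
    "mobility",
    "health_good",
    "family_good",
    "friends_good",
    "retired_yes",
    "female",
    "married",
    "secondary_more",
    "no_children",
)

OUTCOME_TITLES = {
    "MWI_Quality": "Quality of Life",
    "MWI_Satisfaction": "Satisfaction with Life",
    "MWI_Psychological": "Psychological Wellbeing",
}

HC_VARIANTS = ("HC0", "HC1", "HC2", "HC3")


def stars(p: float) -> str:
    """Significance stars: *** p<0.01, ** p<0.05, * p<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass
class RegressionResult:
    """Fit of one outcome: coefficients, robust SEs, inference and fit stats."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    stars: pd.Series
    rsquared: float
    nobs: int
    cov_type: str


def build_design(
    coded: pd.DataFrame, scores: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Numeric design matrix and outcome block with listwise deletion.

    The learning-attitude dummy is 1 for respondents saying the elderly
    should keep learning.  Activity totals enter as raw counts.  Rows
    missing the outcome or any predictor are dropped (listwise), which with
    the instrument's 8 unanswered attitude questions yields 292 usable rows
    out of 300.
    """
    X = pd.DataFrame(index=coded.index)
    learn = coded["learn_elderly"]
    X["learn_elderly"] = (learn == "yes").astype(float).where(learn.notna())
    X["class_total"] = coded["class_total"].astype(float)
    X["places_total"] = coded["places_total"].astype(float)
    X["disability"] = coded["disability"].astype(float)
    X["mobility"] = coded["mobility"].astype(float)
    for src, dst in (
        ("health_good", "health_good"),
        ("family_good", "family_good"),
        ("friends_good", "friends_good"),
    ):
        col = coded[src]
        X[dst] = (col == "good").astype(float).where(col.notna())
    X["retired_yes"] = coded["retired"].astype(float)
    X["female"] = coded["female"].astype(float)
    X["married"] = coded["married"].astype(float)
    edu = coded["education_band"]
    X["secondary_more"] = (edu == "more than secondary").astype(float).where(edu.notna())
    X["no_children"] = coded["no_children"].astype(float)
    X["const"] = 1.0

    missing_cols = [c for c in PREDICTORS if c not in X.columns or X[c].isna().all()]
    if missing_cols:
        raise KeyError(f"predictor column(s) unavailable: {missing_cols}")

    y = scores[list(OUTCOME_TITLES)].copy()
    keep = X.notna().all(axis=1) & y.notna().all(axis=1)
    return X.loc[keep], y.loc[keep]


def fit_ols_robust(
    X: pd.DataFrame, y, variant: str = "HC1", use_t: bool = False, outcome: str = ""
) -> RegressionResult:
    """OLS with a sandwich covariance of the chosen HC variant.

    P-values use the normal approximation by default (``use_t=True`` for the
    t-distribution with n-k degrees of freedom).  Rank-deficient designs
    raise, naming the collinear columns.
    """
    if variant not in HC_VARIANTS:
        raise ValueError(f"variant must be one of {HC_VARIANTS}")
    Xm = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name columns whose removal restores full rank
        bad = [
            c for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(Xm, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    if Xm.shape[0] <= Xm.shape[1]:
        raise ValueError("need more rows than columns")
    res = sm.OLS(np.asarray(y, dtype=float), Xm).fit(cov_type=variant, use_t=use_t)
    idx = pd.Index(X.columns)
    pv = pd.Series(res.pvalues, index=idx)
    return RegressionResult(
        outcome=outcome,
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pv,
        stars=pv.map(stars),
        rsquared=float(res.rsquared),
        nobs=int(res.nobs),
        cov_type=variant,
    )


def fit_all_outcomes(
    coded: pd.DataFrame,
    scores: pd.DataFrame,
    variant: str = "HC1",
    use_t: bool = False,
) -> list[RegressionResult]:
    """Fit the three wellbeing regressions on a common design."""
    X, Y = build_design(coded, scores)
    return [
        fit_ols_robust(X, Y[col], variant=variant, use_t=use_t, outcome=col)
        for col in Y.columns
    ]


def table3_layout(results: list[RegressionResult]) -> str:
    """Render the three fits side by side, journal style.

    Coefficient above robust SE in parentheses, stars appended; R-squared
    and Observations at the bottom; 4 significant figures for coefficients
    and SEs, 3 decimals for R-squared.
    """
    pred_sets = [tuple(r.params.index) for r in results]
    if len(set(pred_sets)) != 1:
        raise ValueError("results have mismatched predictor sets")

    def sig4(v: float) -> str:
        return f"{v:.4g}"

    headers = [""] + [OUTCOME_TITLES.get(r.outcome, r.outcome) for r in results]
    rows: list[list[str]] = []
    order = [p for p in results[0].params.index if p != "const"] + ["const"]
    for p in order:
        name = "Constant" if p == "const" else p
        rows.append([name] + [sig4(r.params[p]) + r.stars[p] for r in results])
        rows.append([""] + [f"({sig4(r.bse[p])})" for r in results])
    rows.append(["Observations"] + [str(r.nobs) for r in results])
    rows.append(["R-squared"] + [f"{r.rsquared:.3f}" for r in results])

    widths = [max(len(row[i]) for row in [headers] + rows) for i in range(len(headers))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(headers, widths)).rstrip()]
    lines.append("-" * len(lines[0]))
    for row in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip())
    lines.append("Robust standard errors in parentheses")
    lines.append("*** p<0.01, ** p<0.05, * p<0.1")
    return "\n".join(lines)


def tidy_results(results: list[RegressionResult]) -> pd.DataFrame:
    """Long-format coefficients/SEs/p-values for machine consumption."""
    frames = []
    for r in results:
        frames.append(
            pd.DataFrame(
                {
                    "outcome": r.outcome,
                    "term": r.params.index,
                    "estimate": r.params.to_numpy(),
                    "robust_se": r.bse.to_numpy(),
                    "statistic": r.tvalues.to_numpy(),
                    "p_value": r.pvalues.to_numpy(),
                    "stars": r.stars.to_numpy(),
                    "r_squared": r.rsquared,
                    "n": r.nobs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class RobustOLS(RegressorMixin, BaseEstimator):
    """OLS + sandwich covariance as an sklearn-style estimator.

    Parameters
    ----------
    cov_type : {"HC0", "HC1", "HC2", "HC3"} — robust variance variant.
    use_t : bool — t-distribution p-values instead of the normal
        approximation.
    add_constant : bool — append an intercept column when X lacks one.

    Attributes
    ----------
    coef_, bse_, tvalues_, pvalues_ : Series indexed by term.
    rsquared_ : float;  nobs_ : int;  result_ : RegressionResult.
    """

    def __init__(self, cov_type: str = "HC1", use_t: bool = False, add_constant: bool = True):
        self.cov_type = cov_type
        self.use_t = use_t
        self.add_constant = add_constant

    def fit(self, X, y) -> "RobustOLS":
        X = pd.DataFrame(X).copy()
        if self.add_constant and "const" not in X.columns:
            X["const"] = 1.0
        self.result_ = fit_ols_robust(X, y, variant=self.cov_type, use_t=self.use_t)
        self.feature_names_in_ = [c for c in X.columns if c != "const"]
        self.coef_ = self.result_.params
        self.bse_ = self.result_.bse
        self.tvalues_ = self.result_.tvalues
        self.pvalues_ = self.result_.pvalues
        self.rsquared_ = self.result_.rsquared
        self.nobs_ = self.result_.nobs
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X).copy()
        if self.add_constant and "const" not in X.columns:
            X["const"] = 1.0
        return np.asarray(X, dtype=float) @ self.coef_.to_numpy()
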