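"""Linear models predicting neuropsychological scores from speech features.

Candidate predictors (the 15 linguistic features plus age and education) are
first screened for multicollinearity: the predictor with the largest variance
inflation factor is removed iteratively while that VIF exceeds five (strictly
greater than).  Each cognitive outcome is then modeled independently on its
complete cases: recursive feature elimination ranked by |t| and sized by
cross-validated RMSE picks the predictor subset, and an ordinary
least-squares fit on standardized predictors reports coefficients, R², AIC
and BIC (Gaussian log-likelihood convention, constant included, as in common
statistical software).  Covariates compete in the elimination like any other
predictor rather than being forced into every model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.model_selection import RepeatedKFold

from .corpus import SCORE_NAMES
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "VIF_THRESHOLD",
    "RegressionResult",
    "ResidualReport",
    "vif_filter",
    "compute_vifs",
    "fit_score_model",
    "rfe_regression",
    "residual_diagnostics",
    "run_regression",
]

VIF_THRESHOLD = 5.0


def compute_vifs(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R²_j) from regressing predictor j on the others.

    An intercept is included in each auxiliary regression.  Perfect
    collinearity yields ``inf``.
    """
    vifs = {}
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        others = np.column_stack(
            [np.ones(len(Xv)), np.delete(Xv, j, axis=1)]
        )
        y = Xv[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        rss = (resid**2).sum()
        if tss == 0:
            vifs[name] = np.inf
            continue
        r2 = 1 - rss / tss
        vifs[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def vif_filter(X: pd.DataFrame, threshold: float = VIF_THRESHOLD):
    """Iteratively drop the worst-VIF predictor while it exceeds ``threshold``.

    The threshold is strict: a predictor whose VIF equals the threshold
    exactly is retained.  Ties (including infinite VIFs from perfect
    collinearity) drop the later-listed predictor.  Returns the survivors in
    their input order together with the VIF history of the removed columns.
    """
    if X.shape[1] < 2:
        return list(X.columns), compute_vifs(X)
    if len(X) <= X.shape[1]:
        raise ValueError("need more rows than predictors for VIF screening")
    cols = list(X.columns)
    while len(cols) > 1:
        vifs = compute_vifs(X[cols])
        worst = vifs.max()
        # strict comparison, with a relative guard so a VIF that equals the
        # threshold up to floating-point noise is retained
        if not worst > threshold * (1 + 1e-9):
            break
        drop = vifs.index[np.flatnonzero(vifs.to_numpy() == worst)[-1]]
        if np.isinf(worst):
            logger.warning("perfectly collinear predictor %r removed", drop)
        else:
            logger.info("dropping %r (VIF %.2f > %g)", drop, worst, threshold)
        cols.remove(drop)
    return cols, compute_vifs(X[cols])


@dataclass
class RegressionResult:
    """One outcome's fitted model and the screening that produced it."""

    outcome: str
    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    aic: float
    bic: float
    n_used: int
    selected: list
    vif_report: pd.Series
    fit: object = field(repr=False, default=None)


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1).replace(0, 1.0)
    return (X - X.mean()) / sd


def fit_score_model(y, X: pd.DataFrame, outcome: str = "score",
                    vif_report: pd.Series | None = None,
                    selected: list | None = None) -> RegressionResult:
    """OLS of an outcome (native scale) on standardized predictors."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"{outcome}: n={n} too small for {p} predictors")
    Z = sm.add_constant(_standardize(X))
    fit = sm.OLS(y, Z).fit()
    return RegressionResult(
        outcome=outcome,
        coefficients=fit.params.drop("const"),
        standard_errors=fit.bse.drop("const"),
        p_values=fit.pvalues.drop("const"),
        r_squared=float(fit.rsquared),
        aic=float(fit.aic),
        bic=float(fit.bic),
        n_used=n,
        selected=selected if selected is not None else list(X.columns),
        vif_report=vif_report if vif_report is not None else compute_vifs(X),
        fit=fit,
    )


def _cv_rmse(y: np.ndarray, X: np.ndarray, cv) -> float:
    errs = []
    for tr, te in cv:
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        beta, _, _, _ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), X[te]]) @ beta
        errs.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
    return float(np.mean(errs))


def _t_ranking(y: np.ndarray, X: pd.DataFrame) -> np.ndarray:
    """|t|-statistic of each predictor in the joint standardized OLS fit."""
    Z = sm.add_constant(_standardize(X))
    fit = sm.OLS(y, Z).fit()
    t = (fit.params / fit.bse).drop("const").abs()
    return t.to_numpy()


def rfe_regression(y, X: pd.DataFrame, cv_folds: int = 10, cv_repeats: int = 5,
                   seed: int = 0) -> list:
    """RFE over subset sizes 1..p minimizing cross-validated RMSE.

    Within each elimination step predictors are re-ranked by |t| in the joint
    fit; the subset size with the smallest mean CV RMSE wins, ties broken
    toward the smaller size.  Returns the winning subset from a final
    elimination pass, in input column order.
    """
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p == 1:
        return list(X.columns)

    def elimination(Xsub: pd.DataFrame):
        cols = list(Xsub.columns)
        order = []
        while len(cols) > 1:
            rank = _t_ranking(y, Xsub[cols])
            worst = int(np.flatnonzero(rank == rank.min())[-1])
            order.append(cols.pop(worst))
        order.append(cols[0])
        return order  # first eliminated first; last entry = most important

    order = elimination(X)
    folds = min(cv_folds, len(y))
    cv = list(
        RepeatedKFold(n_splits=folds, n_repeats=cv_repeats, random_state=seed).split(y)
    )
    rmse = np.zeros(p)
    for s in range(1, p + 1):
        cols = order[p - s:]
        rmse[s - 1] = _cv_rmse(y, X[cols].to_numpy(dtype=float), cv)
    best_size = int(np.argmin(rmse)) + 1  # argmin -> first (smallest) size on ties
    keep = set(order[p - best_size:])
    return [c for c in X.columns if c in keep]


@dataclass
class ResidualReport:
    """Residual shape and trend diagnostics (flags only, no refitting)."""

    skewness: float
    kurtosis: float
    normality_stat: float
    normality_p: float
    trend_slope: float
    curvature_slope: float
    curvature_p: float
    degenerate: bool


def residual_diagnostics(fit) -> ResidualReport:
    """Residual skewness/kurtosis, a normality test, and trend checks.

    The residual-vs-fitted linear slope is ~0 by construction for OLS; the
    curvature check regresses residuals on the squared fitted values and is
    the one that flags a misspecified (nonlinear) mean.  A perfect fit with
    zero residual variance is reported as degenerate.
    """
    resid = np.asarray(fit.resid, dtype=float)
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    if np.allclose(resid, 0) or resid.std() == 0:
        return ResidualReport(0.0, 0.0, np.nan, np.nan, 0.0, 0.0, np.nan, True)
    skew = float(sps.skew(resid))
    kurt = float(sps.kurtosis(resid))
    if len(resid) >= 20:
        stat, pval = sps.normaltest(resid)
    else:
        stat, pval = sps.shapiro(resid)
    slope = float(np.polyfit(fitted, resid, 1)[0]) if np.ptp(fitted) > 0 else 0.0
    if np.ptp(fitted) > 0:
        f2 = fitted**2
        A = sm.add_constant(np.column_stack([fitted, f2]))
        aux = sm.OLS(resid, A).fit()
        curvature, curv_p = float(aux.params[-1]), float(aux.pvalues[-1])
    else:
        curvature, curv_p = 0.0, np.nan
    return ResidualReport(skew, kurt, float(stat), float(pval), slope, curvature, curv_p, False)


def run_regression(cohort: pd.DataFrame, outcomes=SCORE_NAMES,
                   candidates=None, covariates=("age", "education"),
                   vif_threshold: float = VIF_THRESHOLD,
                   cv_folds: int = 10, cv_repeats: int = 5,
                   seed: int = 0) -> dict:
    """VIF screen once, then RFE + OLS per outcome on its complete cases."""
    if candidates is None:
        candidates = [*FEATURE_NAMES, *covariates]
    missing = [c for c in candidates if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing predictor columns {missing}")
    base = cohort.dropna(subset=list(candidates))
    retained, vifs = vif_filter(base[list(candidates)], threshold=vif_threshold)
    results = {}
    for outcome in outcomes:
        if outcome not in cohort.columns:
            logger.warning("outcome %s not in cohort; skipped", outcome)
            continue
        sub = cohort.dropna(subset=[outcome, *retained])
        if len(sub) <= len(retained) + 2:
            logger.warning("outcome %s: too few complete cases (%d)", outcome, len(sub))
            continue
        y = sub[outcome].to_numpy(dtype=float)
        selected = rfe_regression(
            y, sub[retained], cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed
        )
        results[outcome] = fit_score_model(
            y, sub[selected], outcome=outcome, vif_report=vifs, selected=selected
        )
    return results


def regression_table(results: dict) -> pd.DataFrame:
    """Wide outcome-by-predictor coefficient table with fit statistics."""
    rows = {}
    for outcome, res in results.items():
        col = {
            f"{name}": f"{res.coefficients[name]:.2f} ({res.standard_errors[name]:.2f})"
            for name in res.selected
        }
        col["R2"] = f"{res.r_squared:.2f}"
        col["AIC"] = f"{res.aic:.2f}"
        col["BIC"] = f"{res.bic:.2f}"
        col["n"] = res.n_used
        rows[outcome] = col
    return pd.DataFrame(rows)
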