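"""Covariate-adjusted group comparison of the linguistic features.

Each feature is compared between the normal-control and early-AD groups with
an ordinary least-squares model ``feature ~ group + age + education``.  The
feature is standardized first so group coefficients are comparable across
features; standardization leaves the p-values unchanged.  No multiple-testing
correction is applied by default (per-feature raw p-values are reported);
Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = ["compare_groups"]

MIN_PER_GROUP = 5


def compare_groups(cohort: pd.DataFrame, features=FEATURE_NAMES,
                   adjust: bool = False) -> pd.DataFrame:
    """OLS group comparison for each feature, adjusting for age and education.

    Parameters
    ----------
    cohort
        DataFrame with columns ``group`` (NC / early_AD), ``age``,
        ``education`` and one column per feature.  Rows with a missing value
        for a feature are dropped for that feature only.
    features
        Feature columns to compare (default: all 15).
    adjust
        If True, append a Benjamini-Hochberg adjusted p-value column.

    Returns
    -------
    DataFrame with one row per feature: ``group_coefficient`` (standardized
    effect of early_AD vs NC), ``standard_error``, ``p_value``, ``n_used``.
    A feature constant across participants yields NaN with a warning.
    """
    required = {"group", "age", "education"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns {sorted(missing)}")
    counts = cohort["group"].value_counts()
    for g in ("NC", "early_AD"):
        if counts.get(g, 0) < MIN_PER_GROUP:
            raise ValueError(f"need at least {MIN_PER_GROUP} rows in group {g}")

    rows = []
    for name in features:
        if name not in cohort.columns:
            raise ValueError(f"feature column {name!r} not in cohort")
        sub = cohort[[name, "group", "age", "education"]].dropna()
        y = sub[name].to_numpy(dtype=float)
        sd = y.std(ddof=1) if len(y) > 1 else 0.0
        if sd == 0:
            logger.warning("feature %s is constant; p-value undefined", name)
            rows.append((name, np.nan, np.nan, np.nan, len(sub)))
            continue
        z = (y - y.mean()) / sd
        X = pd.DataFrame(
            {
                "early_AD": (sub["group"] == "early_AD").astype(float),
                "age": sub["age"].astype(float),
                "education": sub["education"].astype(float),
            }
        )
        fit = sm.OLS(z, sm.add_constant(X)).fit()
        rows.append(
            (name, fit.params["early_AD"], fit.bse["early_AD"],
             fit.pvalues["early_AD"], int(fit.nobs))
        )
    out = pd.DataFrame(
        rows, columns=["feature", "group_coefficient", "standard_error", "p_value", "n_used"]
    )
    if adjust:
        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    return out
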