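"""Observational stage: covariate-adjusted OLS associations, quartile-group
tests and Benjamini-Hochberg FDR control.

The exposure coefficient reported by :func:`ols_adjusted` is the change in
the outcome per unit increase of the (log-transformed) exposure, adjusted
for age, BMI and season of blood draw unless told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._linalg import covariate_matrix
from .preprocess import _is_skewed

__all__ = [
    "RegressionResult",
    "ols_adjusted",
    "fdr_bh",
    "quartile_groups",
    "group_test",
    "observational_battery",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "bmi", "season")


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    r2: float
    model: str = ""
    covariates: tuple = field(default_factory=tuple)


def ols_adjusted(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    label: str | None = None,
) -> RegressionResult:
    """Exposure coefficient from OLS of ``outcome`` on ``exposure`` plus
    covariates (season as winter-referenced dummies); complete cases only."""
    needed = [outcome, exposure] + [c for c in covariates if c != "season"]
    sub = df.dropna(subset=needed)
    if "season" in covariates:
        sub = sub.dropna(subset=["season"])
    w, names = covariate_matrix(sub, covariates)
    x = np.column_stack([sub[exposure].to_numpy(float), w])
    y = sub[outcome].to_numpy(float)
    if len(y) < x.shape[1] + 1:
        raise ValueError(f"too few complete cases ({len(y)}) for {outcome} ~ {exposure}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient design for {outcome} ~ {exposure}")
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int()[0]
    return RegressionResult(
        beta=float(fit.params[0]),
        se=float(fit.bse[0]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[0]),
        n_used=int(fit.nobs),
        r2=float(fit.rsquared),
        model=label or f"{outcome} ~ {exposure}",
        covariates=tuple(covariates),
    )


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def quartile_groups(x) -> np.ndarray:
    """Quartile labels 1..4 with interpolated cut-points.

    Values exactly at a cut-point fall in the lower group; missing values
    get label 0.
    """
    arr = np.asarray(x, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if np.unique(vals).size < 4:
        raise ValueError("quartile_groups needs at least 4 distinct values")
    cuts = np.quantile(vals, [0.25, 0.5, 0.75])
    labels = np.zeros(arr.shape, dtype=int)
    labels[finite] = np.searchsorted(cuts, vals, side="left") + 1
    return labels


def group_test(y, labels) -> tuple[float, float, str]:
    """One-way location test across groups.

    ANOVA when ``y`` passes the shared normality rule (|skewness| <= 1),
    Kruskal-Wallis otherwise. Returns (statistic, p, method).
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(y) & (labels != 0)
    y, labels = y[keep], labels[keep]
    groups = [y[labels == g] for g in np.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("group_test needs at least 2 non-empty groups")
    if _is_skewed(y):
        stat, p = stats.kruskal(*groups)
        method = "kruskal"
    else:
        if any(g.size < 2 for g in groups):
            raise ValueError("ANOVA needs >= 2 observations per group")
        stat, p = stats.f_oneway(*groups)
        method = "anova"
    return float(stat), float(p), method


def observational_battery(
    df: pd.DataFrame,
    outcomes,
    exposure: str = "log_total_25ohd",
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Unadjusted and adjusted OLS association of each outcome with the
    exposure; adjusted p-values FDR-corrected within the battery (one
    family per battery)."""
    rows = []
    for outcome in outcomes:
        crude = ols_adjusted(df, outcome, exposure, covariates=())
        adj = ols_adjusted(df, outcome, exposure, covariates=covariates)
        rows.append(
            {
                "outcome": outcome,
                "beta_crude": crude.beta,
                "p_crude": crude.p,
                "beta_adjusted": adj.beta,
                "se_adjusted": adj.se,
                "p_adjusted": adj.p,
                "n": adj.n_used,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted_fdr"] = fdr_bh(table["p_adjusted"].to_numpy())
    return table
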