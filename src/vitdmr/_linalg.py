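"""Small shared least-squares helpers used by the first-stage and 2SLS code.

These are deliberately plain numpy (QR-based) so the instrumental-variable
engine is self-contained and fast inside simulation loops; ordinary
covariate-adjusted model fits exposed to users go through statsmodels in
:mod:`vitdmr.assoc`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEASON_LEVELS = ("winter", "spring", "summer", "autumn")  # winter = reference


def covariate_matrix(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept | covariates] with season as dummies.

    The categorical ``season`` column expands to spring/summer/autumn
    indicators with winter as the reference level.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    for cov in covariates:
        if cov == "season":
            season = df["season"].astype(str)
            for level in SEASON_LEVELS[1:]:
                cols.append((season == level).to_numpy(float))
                names.append(f"season_{level}")
        else:
            cols.append(df[cov].to_numpy(float))
            names.append(cov)
    return np.column_stack(cols), names


def ols_fit(y: np.ndarray, x: np.ndarray):
    """OLS via lstsq: returns (beta, cov_beta, residuals, r2, rank)."""
    n, k = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = y - x @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 0.0
    return beta, sigma2 * xtx_inv, resid, r2, dof
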