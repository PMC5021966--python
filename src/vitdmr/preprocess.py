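"""Cohort preprocessing: exclusion cascade, outlier trimming, log transforms,
season coding and descriptive summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusionReport",
    "EmptyCohortError",
    "apply_exclusion_cascade",
    "trim_extremes",
    "log_transform_skewed",
    "season_of",
    "summarize",
    "DEFAULT_LOG_VARIABLES",
    "DEFAULT_SEASON_MAPPING",
]

# Skewed serum variables log-transformed (natural log) before modelling.
DEFAULT_LOG_VARIABLES = ("total_25ohd", "pth", "beta_ctx", "p1np")

# Northern-hemisphere meteorological seasons.
DEFAULT_SEASON_MAPPING = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


class EmptyCohortError(ValueError):
    """Raised when an operation would leave no subjects to analyse."""


def _pct_one_decimal(numerator: int, denominator: int) -> float:
    """Percentage reported to one decimal.

    Follows the clinical-reporting convention of computing the percentage
    to two decimals and then displaying one, rounding half away from zero
    at each step (so 158/2013 -> 7.85 -> 7.9).
    """
    if denominator == 0:
        return 0.0
    x = 100.0 * numerator / denominator
    two = math.floor(abs(x) * 100 + 0.5) / 100
    one = math.floor(two * 10 + 0.5) / 10
    return math.copysign(one, x)


@dataclass(frozen=True)
class ExclusionReport:
    n_enrolled: int
    n_excluded_stage1: int
    n_excluded_stage2: int
    n_final: int
    pct_stage1: float
    pct_stage2: float

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusion_cascade(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop disease/medication-flagged subjects, then abnormal-lab-flagged
    subjects among the survivors.

    Percentages are of the enrolled total, rounded to one decimal. Raises
    :class:`EmptyCohortError` if nobody survives.
    """
    n0 = len(cohort)
    stage1 = cohort["excl_disease_medication"].astype(bool)
    survivors = cohort.loc[~stage1]
    stage2 = survivors["excl_abnormal_lab"].astype(bool)
    final = survivors.loc[~stage2]
    report = ExclusionReport(
        n_enrolled=n0,
        n_excluded_stage1=int(stage1.sum()),
        n_excluded_stage2=int(stage2.sum()),
        n_final=len(final),
        pct_stage1=_pct_one_decimal(int(stage1.sum()), n0),
        pct_stage2=_pct_one_decimal(int(stage2.sum()), n0),
    )
    if len(final) == 0:
        raise EmptyCohortError("no subjects survive the exclusion cascade")
    return final.reset_index(drop=True), report


def trim_extremes(values, z: float = 3.5) -> np.ndarray:
    """Inclusion mask for a single-pass |z| <= ``z`` rule.

    The mean and SD are computed once from all non-missing values; points
    beyond ``z`` sample SDs are masked out. Missing values remain included
    in the mask (they are simply absent, not extreme). A zero-variance
    vector keeps everything.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("trim_extremes needs at least 2 non-missing values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    mask = np.ones_like(x, dtype=bool)
    if sd == 0.0:
        return mask
    mask[finite] = np.abs(x[finite] - mu) <= z * sd
    return mask


def log_transform_skewed(
    cohort: pd.DataFrame, variables=DEFAULT_LOG_VARIABLES, prefix: str = "log_"
) -> pd.DataFrame:
    """Add natural-log columns ``log_<var>`` for the listed variables.

    Originals are retained. Non-positive values are a hard error naming the
    offending subjects, since the downstream models assume the transform is
    defined everywhere it is observed.
    """
    df = cohort.copy()
    for var in variables:
        col = df[var]
        bad = col.notna() & (col <= 0)
        if bad.any():
            ids = (
                df.loc[bad, "subject_id"].tolist()
                if "subject_id" in df
                else df.index[bad].tolist()
            )
            raise ValueError(f"non-positive values in {var!r} for subjects {ids[:10]}")
        df[prefix + var] = np.log(col)
    return df


def season_of(draw_month: int, mapping: dict | None = None) -> str:
    """Season label for a 1-12 draw month (default meteorological mapping)."""
    if not 1 <= int(draw_month) <= 12:
        raise ValueError(f"month must be in 1..12, got {draw_month}")
    mapping = mapping or DEFAULT_SEASON_MAPPING
    return mapping[int(draw_month)]


def _is_skewed(x: np.ndarray, threshold: float = 1.0) -> bool:
    """Normality rule shared across the package: |sample skewness| > 1."""
    if np.unique(x).size == 1:
        return False
    return bool(abs(stats.skew(x, bias=False)) > threshold)


def summarize(cohort: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Descriptive table: mean +/- SD for approximately normal variables,
    median (Q1, Q3) otherwise, plus min and max.

    Quartiles use linear interpolation between order statistics.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    if variables is None:
        variables = [
            c
            for c in cohort.columns
            if pd.api.types.is_numeric_dtype(cohort[c])
            and not c.startswith("excl_")
            and c not in ("subject_id", "draw_month")
        ]
    rows = []
    for var in variables:
        x = cohort[var].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        skewed = _is_skewed(x)
        rows.append(
            {
                "variable": var,
                "branch": "median_iqr" if skewed else "mean_sd",
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "median": float(np.median(x)),
                "q1": float(np.quantile(x, 0.25)),
                "q3": float(np.quantile(x, 0.75)),
                "min": float(x.min()),
                "max": float(x.max()),
                "n": int(x.size),
            }
        )
    return pd.DataFrame(rows)
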