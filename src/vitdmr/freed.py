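"""Free and bioavailable 25OHD from the carrier-binding equilibrium.

Serum 25OHD circulates bound to the vitamin D binding protein (DBP, high
affinity) and albumin (low affinity); only the free plus albumin-bound
("bioavailable") pool is thought to be available to most tissues. Given
measured total 25OHD, DBP and albumin plus the two affinity constants, the
free concentration F satisfies the mass balance

    T = F + ka_alb [Alb] F + ka_dbp [DBP]_free F,

all in mol/L. Two solvers are provided:

* ``free_25ohd_linear`` - the trace-ligand form that treats the carriers as
  unsaturable, F = T / (1 + ka_alb [Alb] + ka_dbp [DBP]); this is the
  common practice in the free-vitamin-D literature and the package default.
* ``free_25ohd_exact`` - treats DBP binding as saturable; the mass balance
  becomes quadratic in F with a unique non-negative root.

Both agree to first order whenever total 25OHD is far below the DBP binding
capacity, which holds at physiologic concentrations (~5e-8 M total vs
~2.6e-6 M DBP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BindingConstants

__all__ = [
    "to_molar",
    "FreeDResult",
    "free_25ohd_linear",
    "free_25ohd_exact",
    "add_free_d_columns",
]

_UNIT_TO_G_PER_L = {"ng/mL": 1e-6, "pg/mL": 1e-9, "mg/L": 1e-3, "g/L": 1.0}


def to_molar(concentration, unit: str, mw: float):
    """Convert a mass concentration to mol/L.

    Supported units: ng/mL, pg/mL, mg/L, g/L.
    """
    if unit not in _UNIT_TO_G_PER_L:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_G_PER_L)}")
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c * _UNIT_TO_G_PER_L[unit] / mw
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FreeDResult:
    """Partition of total 25OHD across the free and carrier-bound pools.

    ``free + albumin_bound + dbp_bound == total`` (ng/mL scale) and
    ``bioavailable = free + albumin_bound``.
    """

    free_pg_ml: np.ndarray | float
    bioavailable_ng_ml: np.ndarray | float
    dbp_bound_ng_ml: np.ndarray | float
    albumin_bound_ng_ml: np.ndarray | float
    solver: str


def _molar_inputs(total, dbp, albumin, k: BindingConstants):
    k.validate()
    t = to_molar(total, "ng/mL", k.mw_25ohd)
    d = to_molar(dbp, "mg/L", k.mw_dbp)
    a = to_molar(albumin, "g/L", k.mw_alb)
    return np.asarray(t, float), np.asarray(d, float), np.asarray(a, float)


def _package(f_molar, t_molar, alb_term, k: BindingConstants, solver: str) -> FreeDResult:
    ng = k.mw_25ohd * 1e6  # mol/L -> ng/mL
    alb_bound = f_molar * alb_term
    dbp_bound = t_molar - f_molar - alb_bound
    def _f(x):
        x = np.asarray(x, float)
        return float(x) if x.ndim == 0 else x
    return FreeDResult(
        free_pg_ml=_f(f_molar * ng * 1e3),
        bioavailable_ng_ml=_f((f_molar + alb_bound) * ng),
        dbp_bound_ng_ml=_f(dbp_bound * ng),
        albumin_bound_ng_ml=_f(alb_bound * ng),
        solver=solver,
    )


def free_25ohd_linear(total, dbp, albumin, k: BindingConstants | None = None) -> FreeDResult:
    """Trace-ligand (unsaturable-carrier) solution.

    F = T / (1 + ka_alb [Alb] + ka_dbp [DBP]); bioavailable =
    F (1 + ka_alb [Alb]). Inputs: total 25OHD in ng/mL, DBP in mg/L,
    albumin in g/L; broadcastable arrays or scalars.
    """
    k = k or BindingConstants()
    t, d, a = _molar_inputs(total, dbp, albumin, k)
    alb_term = k.ka_alb * a
    f = t / (1.0 + alb_term + k.ka_dbp * d)
    return _package(f, t, alb_term, k, "linear")


def free_25ohd_exact(total, dbp, albumin, k: BindingConstants | None = None) -> FreeDResult:
    """Saturable-DBP solution of the full mass balance.

    Solves T = F (1 + ka_alb [Alb]) + [DBP]_tot ka_dbp F / (1 + ka_dbp F),
    a quadratic in F with exactly one non-negative root:

        a_c k F^2 + (a_c + k ([DBP]_tot - T)) F - T = 0,

    where a_c = 1 + ka_alb [Alb] and k = ka_dbp.
    """
    k_ = k or BindingConstants()
    t, d, a = _molar_inputs(total, dbp, albumin, k_)
    alb_term = k_.ka_alb * a
    a_c = 1.0 + alb_term
    ka = k_.ka_dbp
    # F = (-b + sqrt(b^2 + 4 a_c ka T)) / (2 a_c ka); discriminant >= b^2 so
    # the root is non-negative for every valid input
    b = a_c + ka * (d - t)
    disc = b * b + 4.0 * a_c * ka * t
    f = np.where(t == 0.0, 0.0, (-b + np.sqrt(disc)) / (2.0 * a_c * ka))
    f = np.clip(f, 0.0, None)
    return _package(f, t, alb_term, k_, "exact")


def add_free_d_columns(
    cohort: pd.DataFrame,
    k: BindingConstants | None = None,
    solver: str = "linear",
    total_col: str = "total_25ohd",
    dbp_col: str = "dbp",
    albumin_col: str = "albumin",
) -> pd.DataFrame:
    """Append ``free_25ohd`` (pg/mL) and ``bioavailable_25ohd`` (ng/mL)."""
    if solver == "linear":
        fn = free_25ohd_linear
    elif solver == "exact":
        fn = free_25ohd_exact
    else:
        raise ValueError("solver must be 'linear' or 'exact'")
    df = cohort.copy()
    res = fn(
        df[total_col].to_numpy(float),
        df[dbp_col].to_numpy(float),
        df[albumin_col].to_numpy(float),
        k,
    )
    df["free_25ohd"] = res.free_pg_ml
    df["bioavailable_25ohd"] = res.bioavailable_ng_ml
    return df
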