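"""Allele-score two-stage least squares, weak-instrument diagnostics and the
Hausman endogeneity test.

The causal stage regresses each clinical outcome on the genetically
predicted log 25OHD level. Three model variants are supported: a single
lead-SNP instrument, an unweighted allele score (sum of effect-allele
counts across the instruments), and a weighted allele score using external
per-allele weights. The 2SLS exposure coefficient is computed two ways -
the control-function form (outcome on fitted exposure + covariates +
first-stage residual) and the canonical matrix form - and the two are
cross-asserted; reported standard errors come from the matrix form with
homoskedastic variance based on the structural residual.

Instrument strength is summarised by the incremental first-stage R^2, the
partial F for the score term, and the closed-form conversion
F = [(n - 1 - k)/k] r^2 / (1 - r^2); the approximate relative bias of 2SLS
toward OLS is 1/F, with F <= 10 flagged as weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import covariate_matrix, ols_fit
from .assoc import DEFAULT_COVARIATES, RegressionResult, fdr_bh, ols_adjusted
from .config import DEFAULT_INSTRUMENT_WEIGHTS, DEFAULT_INSTRUMENTS, DEFAULT_LEAD_SNP

__all__ = [
    "InstrumentSet",
    "FirstStageResult",
    "MRResult",
    "HausmanResult",
    "build_allele_score",
    "first_stage",
    "f_from_r2",
    "relative_bias",
    "tsls",
    "hausman",
    "run_mr_battery",
    "OrientationWarning",
]

WEAK_F_THRESHOLD = 10.0


class OrientationWarning(UserWarning):
    """Allele score positively associated with the exposure: the effect
    alleles are probably not oriented to the exposure-lowering allele."""


@dataclass(frozen=True)
class InstrumentSet:
    """Instrument definition for one MR model variant."""

    snp_ids: tuple[str, ...]
    score_type: str  # "single" | "unweighted" | "weighted"
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.score_type not in ("single", "unweighted", "weighted"):
            raise ValueError(f"unknown score type {self.score_type!r}")
        if self.score_type == "single" and len(self.snp_ids) != 1:
            raise ValueError("single-instrument model takes exactly one SNP")
        if (self.score_type == "weighted") != (self.weights is not None):
            raise ValueError("weights must be given iff score_type == 'weighted'")
        if self.weights is not None and len(self.weights) != len(self.snp_ids):
            raise ValueError("weights length must match snp_ids")


def build_allele_score(genotypes: pd.DataFrame, instruments: InstrumentSet) -> pd.Series:
    """Per-subject allele score.

    unweighted: sum of effect-allele dosages; weighted: weighted sum;
    single: the lone dosage. Subjects missing any instrument dosage get NaN
    (they are dropped listwise downstream).
    """
    missing = [s for s in instruments.snp_ids if s not in genotypes.columns]
    if missing:
        raise KeyError(f"instrument SNPs absent from genotype matrix: {missing}")
    sub = genotypes[list(instruments.snp_ids)].to_numpy(dtype=float)
    if instruments.score_type == "weighted":
        score = sub @ np.asarray(instruments.weights, dtype=float)
    else:
        score = sub.sum(axis=1)
    score = np.where(np.isnan(sub).any(axis=1), np.nan, score)
    return pd.Series(score, index=genotypes.index, name=f"score_{instruments.score_type}")


@dataclass(frozen=True)
class FirstStageResult:
    fitted: np.ndarray
    residuals: np.ndarray
    coef: float
    se: float
    incremental_r2: float
    partial_f: float
    n: int


def first_stage(log_exposure, score, covariate_design: np.ndarray) -> FirstStageResult:
    """Regress the log exposure on score + covariates.

    ``incremental_r2`` is the R^2 gain of adding the score over the
    covariates-only model; ``partial_f`` is the 1-df F (squared t) for the
    score term.
    """
    x = np.asarray(log_exposure, dtype=float)
    z = np.asarray(score, dtype=float)
    if np.std(z) == 0:
        raise ValueError("zero-variance allele score")
    design = np.column_stack([z, covariate_design])
    beta, cov, resid, r2_full, _ = ols_fit(x, design)
    _, _, _, r2_cov, _ = ols_fit(x, covariate_design)
    coef = float(beta[0])
    se = float(np.sqrt(cov[0, 0]))
    return FirstStageResult(
        fitted=design @ beta,
        residuals=resid,
        coef=coef,
        se=se,
        incremental_r2=max(r2_full - r2_cov, 0.0),
        partial_f=(coef / se) ** 2,
        n=x.size,
    )


def f_from_r2(r2: float, n: int, k: int = 1) -> float:
    """Closed-form first-stage F from the incremental R^2.

    F = [(n - 1 - k)/k] * r2 / (1 - r2) for k instrument terms and n
    subjects.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("need k >= 1 and n > k + 1")
    return (n - 1 - k) / k * r2 / (1.0 - r2)


def relative_bias(f_stat: float) -> float:
    """Approximate relative bias of 2SLS toward OLS: 1/F.

    Instruments with F <= 10 are conventionally flagged weak (bias above
    10% of the OLS bias).
    """
    if f_stat <= 0:
        raise ValueError("F must be > 0")
    return 1.0 / f_stat


def is_weak(f_stat: float) -> bool:
    return f_stat <= WEAK_F_THRESHOLD


def sample_size_inflation(se_ratio: float) -> float:
    """Fractional sample-size increase needed to shrink the SE by a factor.

    Since the SE scales as n^-1/2, achieving ``se_ratio`` (new SE / old SE)
    requires n to grow by 1/se_ratio^2 - 1; e.g. a 20% SE decrease
    (se_ratio = 0.8) needs a 56% larger sample.
    """
    if not 0.0 < se_ratio:
        raise ValueError("se_ratio must be > 0")
    return 1.0 / se_ratio**2 - 1.0


@dataclass(frozen=True)
class MRResult:
    model: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    first_stage_r2: float
    first_stage_f: float
    f_analytic: float
    relative_bias: float
    weak_instrument: bool
    n_used: int
    covariates: tuple = field(default_factory=tuple)


def tsls(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    score,
    covariates=DEFAULT_COVARIATES,
    label: str = "",
) -> MRResult:
    """Two-stage least squares of ``outcome`` on the instrumented exposure.

    The exposure coefficient is computed by both the control-function and
    canonical matrix routes and cross-asserted to 1e-8; the matrix route's
    homoskedastic SE (structural residuals, t reference with n - k df) is
    reported.
    """
    work = df.copy()
    work["_score"] = np.asarray(score, dtype=float)
    needed = [outcome, exposure, "_score"] + [c for c in covariates if c != "season"]
    work = work.dropna(subset=needed)
    if "season" in covariates:
        work = work.dropna(subset=["season"])
    w, _ = covariate_matrix(work, covariates)
    y = work[outcome].to_numpy(float)
    x = work[exposure].to_numpy(float)
    z = work["_score"].to_numpy(float)

    fs = first_stage(x, z, w)
    if fs.coef == 0.0:
        raise ValueError("degenerate first stage: zero score coefficient")

    # matrix 2SLS: X = [x | W], Z = [score | W]; beta = (X' Pz X)^-1 X' Pz y
    xmat = np.column_stack([x, w])
    zmat = np.column_stack([z, w])
    ztz = zmat.T @ zmat
    pz_x = zmat @ np.linalg.solve(ztz, zmat.T @ xmat)
    xpx = xmat.T @ pz_x
    beta_all = np.linalg.solve(xpx, pz_x.T @ y)
    n, k = xmat.shape
    resid_struct = y - xmat @ beta_all
    sigma2 = resid_struct @ resid_struct / (n - k)
    cov = sigma2 * np.linalg.inv(xpx)
    beta_iv = float(beta_all[0])
    se = float(np.sqrt(cov[0, 0]))

    # control-function route: y on [x_hat | W | v_hat], coefficient on x_hat.
    # With a perfectly predictive score the residual column vanishes and the
    # CF design is singular; 2SLS then equals OLS exactly and the
    # cross-check is vacuous, so it is skipped.
    resid_scale = np.linalg.norm(fs.residuals)
    if resid_scale > 1e-8 * max(1.0, np.linalg.norm(x - x.mean())):
        cf_design = np.column_stack([fs.fitted, w, fs.residuals])
        cf_beta, _, _, _, _ = ols_fit(y, cf_design)
        beta_cf = float(cf_beta[0])
        if abs(beta_cf - beta_iv) > 1e-8 * max(1.0, abs(beta_iv)):
            raise AssertionError(
                f"control-function ({beta_cf}) and matrix-2SLS ({beta_iv}) "
                "exposure coefficients disagree"
            )

    tq = stats.t.ppf(0.975, n - k)
    p = 2.0 * stats.t.sf(abs(beta_iv / se), n - k)
    f_analytic = f_from_r2(fs.incremental_r2, n, 1)
    return MRResult(
        model=label,
        outcome=outcome,
        beta=beta_iv,
        se=se,
        ci_low=beta_iv - tq * se,
        ci_high=beta_iv + tq * se,
        p=float(p),
        first_stage_r2=fs.incremental_r2,
        first_stage_f=fs.partial_f,
        f_analytic=f_analytic,
        relative_bias=relative_bias(f_analytic) if f_analytic > 0 else np.inf,
        weak_instrument=is_weak(fs.partial_f),
        n_used=n,
        covariates=tuple(covariates),
    )


@dataclass(frozen=True)
class HausmanResult:
    stat: float
    p: float | None
    status: str  # "ok" | "degenerate"


def hausman(ols_res: RegressionResult, iv_res: MRResult) -> HausmanResult:
    """Hausman contrast of the IV and OLS exposure coefficients.

    stat = (b_iv - b_ols)^2 / (se_iv^2 - se_ols^2), referred to chi2 with
    1 df. Both fits must use the same subjects; a non-positive variance
    difference yields status "degenerate" with no p-value.
    """
    if ols_res.n_used != iv_res.n_used:
        raise ValueError(
            f"OLS (n={ols_res.n_used}) and IV (n={iv_res.n_used}) fits use "
            "different samples"
        )
    var_diff = iv_res.se**2 - ols_res.se**2
    diff = iv_res.beta - ols_res.beta
    if var_diff <= 0:
        return HausmanResult(stat=np.nan, p=None, status="degenerate")
    stat = diff * diff / var_diff
    return HausmanResult(stat=float(stat), p=float(stats.chi2.sf(stat, df=1)), status="ok")


DEFAULT_MR_OUTCOMES = ("bmd_l1l4", "bmd_fn", "bmd_th", "log_pth", "log_p1np")


def default_instrument_models(
    instruments=DEFAULT_INSTRUMENTS,
    lead_snp: str = DEFAULT_LEAD_SNP,
    weights: dict | None = None,
) -> dict[str, InstrumentSet]:
    """The three standard model variants keyed by label."""
    weights = weights or DEFAULT_INSTRUMENT_WEIGHTS
    return {
        "single": InstrumentSet((lead_snp,), "single"),
        "unweighted": InstrumentSet(tuple(instruments), "unweighted"),
        "weighted": InstrumentSet(
            tuple(instruments), "weighted",
            tuple(weights[s] for s in instruments),
        ),
    }


def run_mr_battery(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    outcomes=DEFAULT_MR_OUTCOMES,
    exposure: str = "log_total_25ohd",
    covariates=DEFAULT_COVARIATES,
    instruments=DEFAULT_INSTRUMENTS,
    lead_snp: str = DEFAULT_LEAD_SNP,
    weights: dict | None = None,
    include_beta_ctx: bool = False,
) -> pd.DataFrame:
    """Full causal battery: every outcome x {single, unweighted, weighted}.

    Genotype rows must align positionally with cohort rows. Subjects
    missing any instrument dosage are dropped listwise for all models so n
    is constant within the battery; each model's OLS counterpart is fit on
    the same subjects and contrasted with the Hausman test, whose p-values
    are FDR-adjusted within the battery. Beta-CTX is excluded from the
    default outcome set (no robust adjusted observational association to
    follow up) unless ``include_beta_ctx``.
    """
    if len(genotypes) != len(cohort):
        raise ValueError("genotype rows not aligned with cohort rows")
    outcomes = list(outcomes)
    if include_beta_ctx and "log_beta_ctx" not in outcomes:
        outcomes.append("log_beta_ctx")
    models = default_instrument_models(instruments, lead_snp, weights)

    scores = {
        name: build_allele_score(genotypes.reset_index(drop=True), inst)
        for name, inst in models.items()
    }
    score_mat = np.column_stack([s.to_numpy() for s in scores.values()])
    keep = ~np.isnan(score_mat).any(axis=1)
    work = cohort.reset_index(drop=True).loc[keep].reset_index(drop=True)
    scores = {name: s.loc[keep].reset_index(drop=True) for name, s in scores.items()}

    # orientation guard: effect alleles are exposure-lowering by convention
    chk_cols = [exposure] + [c for c in covariates if c != "season"]
    if "season" in covariates:
        chk_cols.append("season")
    x_chk = work.dropna(subset=chk_cols)
    w_cov, _ = covariate_matrix(x_chk, covariates)
    fs_chk = first_stage(
        x_chk[exposure].to_numpy(float),
        scores["unweighted"].loc[x_chk.index].to_numpy(float),
        w_cov,
    )
    if fs_chk.coef > 0 and fs_chk.partial_f > 10.83:  # ~p < 0.001
        warnings.warn(
            "allele score is positively associated with the exposure; check "
            "effect-allele orientation",
            OrientationWarning,
            stacklevel=2,
        )

    rows = []
    for outcome in outcomes:
        for name, inst in models.items():
            res = tsls(work, outcome, exposure, scores[name], covariates, label=name)
            complete = work.dropna(
                subset=[outcome, exposure]
                + [c for c in covariates if c != "season"]
                + (["season"] if "season" in covariates else [])
            )
            ols_res = ols_adjusted(complete, outcome, exposure, covariates)
            h = hausman(ols_res, res)
            rows.append(
                {
                    "outcome": outcome,
                    "model": name,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p,
                    "first_stage_r2": res.first_stage_r2,
                    "first_stage_f": res.first_stage_f,
                    "f_analytic": res.f_analytic,
                    "relative_bias": res.relative_bias,
                    "weak_instrument": res.weak_instrument,
                    "beta_ols": ols_res.beta,
                    "se_ols": ols_res.se,
                    "hausman_stat": h.stat,
                    "hausman_p": h.p if h.p is not None else np.nan,
                    "hausman_status": h.status,
                    "n": res.n_used,
                }
            )
    table = pd.DataFrame(rows)
    ok = table["hausman_status"] == "ok"
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = fdr_bh(table.loc[ok, "hausman_p"].to_numpy())
    table["hausman_p_fdr"] = adj
    return table
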