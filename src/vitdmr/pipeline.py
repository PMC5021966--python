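"""End-to-end orchestration: preprocess -> biochemistry -> genetics QC ->
observational models -> MR engine, with all tables written to disk.

The command-line layer in :mod:`vitdmr.cli` is a thin wrapper around
:func:`run_pipeline` and :func:`simulate_to_dir`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__, io, qc, report
from .assoc import observational_battery
from .config import RunConfig
from .freed import add_free_d_columns
from .mr import run_mr_battery
from .preprocess import (
    DEFAULT_LOG_VARIABLES,
    apply_exclusion_cascade,
    log_transform_skewed,
    summarize,
    trim_extremes,
)
from .synthetic import generate_cohort

log = logging.getLogger("vitdmr")

# variables screened for extreme values; skewed ones on their log scale
TRIM_VARIABLES = (
    "age", "bmi", "log_total_25ohd", "log_pth", "log_p1np", "log_beta_ctx",
    "alp", "ca", "p", "cr", "bun", "bmd_l1l4", "bmd_fn", "bmd_th",
)
OBSERVATIONAL_OUTCOMES = (
    "bmd_l1l4", "bmd_fn", "bmd_th", "log_pth", "log_beta_ctx", "log_p1np"
)


def simulate_to_dir(config: RunConfig, out_dir=None) -> dict:
    """Generate a synthetic cohort and write cohort/genotype/truth TSVs."""
    out = io.ensure_dir(out_dir or config.out_dir)
    bundle = generate_cohort(config.synthetic)
    io.write_cohort_tsv(bundle.cohort, out / "cohort.tsv")
    io.write_genotypes_tsv(bundle.genotypes, out / "genotypes.tsv")
    io.write_truth_tsv(bundle.truth, out / "truth.tsv")
    manifest = {
        "tool": "vitdmr",
        "version": __version__,
        "command": "simulate",
        "seed": config.synthetic.seed,
        "n_subjects": config.synthetic.n_subjects,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"out_dir": str(out), **manifest}


def run_pipeline(
    config: RunConfig,
    cohort: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    stages=("preprocess", "biochem", "qc", "observational", "mr"),
    out_dir=None,
) -> dict:
    """Execute the analysis stages and return all result tables.

    ``cohort``/``genotypes`` default to the files named in the config; both
    must carry one row per enrolled subject, genotypes indexed by position
    matching ``subject_id``.
    """
    config.validate()
    out = io.ensure_dir(out_dir or config.out_dir)
    if cohort is None:
        if config.cohort_path is None:
            raise ValueError("no cohort given: set cohort_path or pass a DataFrame")
        cohort = io.read_cohort_tsv(config.cohort_path)
    if genotypes is None:
        if config.genotype_path is None:
            raise ValueError("no genotypes given: set genotype_path or pass a DataFrame")
        genotypes = io.read_genotypes_tsv(config.genotype_path)
    genotypes = genotypes.reset_index(drop=True)
    results: dict = {"manifest": {
        "tool": "vitdmr",
        "version": __version__,
        "command": "run",
        "seed": config.seed,
        "stages": list(stages),
        "free_d_solver": config.free_d_solver,
        "instruments": list(config.instruments),
        "lead_snp": config.lead_snp,
    }}

    df = cohort.reset_index(drop=True)
    if "preprocess" in stages:
        try:
            df, excl = apply_exclusion_cascade(df)
        except Exception as err:  # annotate which stage failed
            raise RuntimeError(f"stage preprocess failed: {err}") from err
        genotypes = genotypes.iloc[df["subject_id"].to_numpy()].reset_index(drop=True)
        results["exclusion_report"] = excl
        log.info("exclusion cascade: %s", report.render_exclusion_report(excl).replace("\n", "; "))

        df = log_transform_skewed(df, [v for v in DEFAULT_LOG_VARIABLES if v in df])
        trim_counts = {}
        for var in TRIM_VARIABLES:
            if var not in df:
                continue
            mask = trim_extremes(df[var].to_numpy(float), z=config.trim_z)
            n_out = int((~mask).sum())
            if n_out:
                df.loc[~mask, var] = np.nan
            trim_counts[var] = n_out
        results["trim_counts"] = trim_counts
        log.info("extreme-value trimming (>%.1f SD): %s", config.trim_z, trim_counts)

    if "biochem" in stages:
        df = add_free_d_columns(df, config.binding, solver=config.free_d_solver)

    results["descriptives"] = summarize(df)

    if "qc" in stages:
        qc_table = qc.snp_qc_table(
            genotypes,
            hwe_p_threshold=config.hwe_p_threshold,
            rate_threshold=config.genotyping_rate_threshold,
        )
        results["snp_qc"] = qc_table
        passing = set(qc_table.loc[qc_table["qc_pass"], "snp_id"])
        candidates = [s for s in config.instruments if s in passing]
        others = [s for s in genotypes.columns if s not in config.instruments and s in passing]
        proxies = qc.select_proxies(
            candidates, others, genotypes, r2_threshold=config.proxy_r2_threshold
        )
        results["proxies"] = proxies
        independent = [s for s in others if s not in proxies]
        snp_rows = []
        for snp in independent:
            res = qc.snp_exposure_assoc(df, genotypes[snp].to_numpy(), snp)
            snp_rows.append({"snp_id": snp, "beta": res.beta, "se": res.se,
                             "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p})
        results["snp_exposure"] = pd.DataFrame(snp_rows)
        results["validity_screen"] = qc.iv_validity_screen(
            df, genotypes, candidates, alpha=config.fdr_alpha
        )

    if "observational" in stages:
        exposures = ["log_total_25ohd"]
        if "biochem" in stages:
            df_obs = log_transform_skewed(df, ["free_25ohd", "bioavailable_25ohd"])
            exposures += ["log_free_25ohd", "log_bioavailable_25ohd"]
        else:
            df_obs = df
        obs = {
            exp: observational_battery(df_obs, OBSERVATIONAL_OUTCOMES, exposure=exp)
            for exp in exposures
        }
        results["observational"] = obs["log_total_25ohd"]
        results["observational_all"] = obs

    if "mr" in stages:
        battery = run_mr_battery(
            df,
            genotypes,
            instruments=config.instruments,
            lead_snp=config.lead_snp,
            weights=config.weights,
            include_beta_ctx=config.include_beta_ctx,
        )
        results["mr_battery"] = battery

    _write_outputs(results, out)
    return results


def _write_outputs(results: dict, out) -> None:
    manifest = dict(results["manifest"])
    if "exclusion_report" in results:
        rep = results["exclusion_report"]
        manifest["exclusion_report"] = rep.to_dict()
        (out / "exclusion_report.json").write_text(json.dumps(rep.to_dict(), indent=2))
    if "trim_counts" in results:
        manifest["trim_counts"] = results["trim_counts"]
    results["descriptives"].to_csv(out / "descriptives.tsv", sep="\t", index=False)
    text = [report.render_descriptives(results["descriptives"])]
    if "snp_qc" in results:
        results["snp_qc"].to_csv(out / "snp_qc.tsv", sep="\t", index=False)
        results["snp_exposure"].to_csv(out / "snp_exposure.tsv", sep="\t", index=False)
        results["validity_screen"].to_csv(out / "validity_screen.tsv", sep="\t", index=False)
        manifest["proxies"] = {k: list(v) for k, v in results["proxies"].items()}
    if "observational" in results:
        results["observational"].to_csv(out / "observational.tsv", sep="\t", index=False)
        text.append(report.render_observational(results["observational"]))
    if "mr_battery" in results:
        results["mr_battery"].to_csv(out / "mr_battery.tsv", sep="\t", index=False)
        text.append(report.render_instrument_strength(results["mr_battery"]))
        text.append(report.render_mr(results["mr_battery"]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.txt").write_text("\n\n".join(text) + "\n")
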