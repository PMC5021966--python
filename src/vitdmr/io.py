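"""Tab-separated readers and writers for the cohort, genotype and truth
tables.

The cohort TSV uses a fixed, documented column order; the genotype TSV has
subjects as rows (first column ``subject``) and SNP ids as the header; the
truth sidecar holds the latent confounder and generating parameters and is
never read by any analysis module.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

COHORT_COLUMNS = [
    "subject_id", "age", "height", "weight", "bmi", "draw_month", "season",
    "total_25ohd", "dbp", "albumin", "free_25ohd", "bioavailable_25ohd",
    "pth", "p1np", "beta_ctx", "alp", "ca", "p", "cr", "bun",
    "bmd_l1l4", "bmd_fn", "bmd_th",
    "excl_disease_medication", "excl_abnormal_lab",
]


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.rename_axis("subject").to_csv(path, sep="\t")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
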