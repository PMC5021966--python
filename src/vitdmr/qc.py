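"""SNP-level quality control and instrument screening.

Covers allele-frequency and Hardy-Weinberg checks, genotyping-rate
filtering, LD estimation on unphased dosages (composite correlation by
default, EM haplotype frequencies as a cross-check), proxy selection, the
per-SNP exposure association, and the instrument-validity screen against
confounders and outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import RegressionResult, fdr_bh, ols_adjusted

__all__ = [
    "allele_freq",
    "hwe_chisq",
    "genotype_counts",
    "genotyping_rate",
    "snp_qc_table",
    "ld_r2",
    "select_proxies",
    "snp_exposure_assoc",
    "iv_validity_screen",
    "read_dosage_tsv",
    "read_vcf_dosages",
]


def _clean(dosages) -> np.ndarray:
    x = np.asarray(dosages, dtype=float)
    obs = x[np.isfinite(x)]
    if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise ValueError("dosages must be 0, 1, 2 or missing")
    return x


def allele_freq(dosages) -> tuple[float, float]:
    """(effect-allele frequency, minor-allele frequency) of one SNP column."""
    x = _clean(dosages)
    obs = x[np.isfinite(x)]
    if obs.size == 0:
        raise ValueError("all dosages missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(f), float(min(f, 1.0 - f))


def genotype_counts(dosages) -> tuple[int, int, int]:
    """(n0, n1, n2) carriers of 0/1/2 effect alleles, missing excluded."""
    x = _clean(dosages)
    obs = x[np.isfinite(x)].astype(int)
    return tuple(int(np.sum(obs == g)) for g in (0, 1, 2))


def hwe_chisq(counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg
    proportions at the sample allele frequency.

    Monomorphic loci are defined to have chi2 = 0, p = 1 (with a warning):
    a fixed locus carries no information about genotyping error.
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("empty genotype counts")
    p = (n1 + 2 * n2) / (2.0 * n)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic locus: HWE p defined as 1", stacklevel=2)
        return 0.0, 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotyping_rate(dosages) -> float:
    """Fraction of non-missing dosages in a SNP column."""
    x = np.asarray(dosages, dtype=float)
    if x.size == 0:
        raise ValueError("empty dosage column")
    return float(np.isfinite(x).mean())


def snp_qc_table(
    genotypes: pd.DataFrame,
    hwe_p_threshold: float = 0.05,
    rate_threshold: float = 0.90,
    gene_labels: dict | None = None,
) -> pd.DataFrame:
    """Per-SNP QC summary; ``qc_pass`` requires genotyping rate strictly
    above ``rate_threshold`` AND HWE p strictly above ``hwe_p_threshold``."""
    rows = []
    for snp in genotypes.columns:
        col = genotypes[snp]
        rate = genotyping_rate(col)
        f, maf = allele_freq(col)
        chi2, p = hwe_chisq(genotype_counts(col))
        rows.append(
            {
                "snp_id": snp,
                "gene": (gene_labels or {}).get(snp, ""),
                "effect_allele_freq": f,
                "maf": maf,
                "hwe_chi2": chi2,
                "hwe_p": p,
                "genotyping_rate": rate,
                "qc_pass": bool(rate > rate_threshold and p > hwe_p_threshold),
            }
        )
    return pd.DataFrame(rows)


def _em_haplotype_r2(a: np.ndarray, b: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> float:
    """r^2 from EM-estimated two-locus haplotype frequencies under HWE.

    Unphased double heterozygotes are ambiguous between the cis and trans
    phase; EM splits them according to the current haplotype frequencies.
    """
    a = a.astype(int)
    b = b.astype(int)
    pa = a.mean() / 2.0
    pb = b.mean() / 2.0
    # haplotype freqs (h11, h10, h01, h00), start at linkage equilibrium
    h11, h10, h01, h00 = pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)
    # 3x3 genotype table; every cell except the double heterozygote (1,1)
    # has a determined phase
    tab = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            tab[i, j] = np.sum((a == i) & (b == j))
    n_dh = tab[1, 1]
    c11 = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    c10 = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    c01 = 2 * tab[0, 2] + tab[1, 2] + tab[0, 1]
    c00 = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    for _ in range(max_iter):
        cis = h11 * h00
        trans = h10 * h01
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        t11 = c11 + w * n_dh
        t00 = c00 + w * n_dh
        t10 = c10 + (1 - w) * n_dh
        t01 = c01 + (1 - w) * n_dh
        total = t11 + t10 + t01 + t00
        new = (t11 / total, t10 / total, t01 / total, t00 / total)
        if max(abs(new[0] - h11), abs(new[1] - h10), abs(new[2] - h01), abs(new[3] - h00)) < tol:
            h11, h10, h01, h00 = new
            break
        h11, h10, h01, h00 = new
    pa_hat = h11 + h10
    pb_hat = h11 + h01
    denom = pa_hat * (1 - pa_hat) * pb_hat * (1 - pb_hat)
    if denom <= 0:
        raise ValueError("monomorphic locus in EM r2")
    d = h11 - pa_hat * pb_hat
    return float(d * d / denom)


def ld_r2(dosages_a, dosages_b, method: str = "composite") -> float:
    """Squared correlation between two dosage columns.

    ``composite`` (default): squared Pearson correlation of the unphased
    dosage vectors. ``em``: r^2 from EM-estimated haplotype frequencies
    assuming HWE. Subjects missing either dosage are dropped.
    """
    a = _clean(dosages_a)
    b = _clean(dosages_b)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need >= 2 subjects with both dosages observed")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance dosage vector")
    if method == "composite":
        r = np.corrcoef(a, b)[0, 1]
        return float(min(r * r, 1.0))
    if method == "em":
        return min(_em_haplotype_r2(a, b), 1.0)
    raise ValueError("method must be 'composite' or 'em'")


def select_proxies(
    candidate_ivs,
    other_snps,
    genotypes: pd.DataFrame,
    r2_threshold: float = 0.80,
    method: str = "composite",
) -> dict[str, tuple[str, float]]:
    """Map each non-candidate SNP in high LD with a candidate IV to that
    candidate (highest r^2 wins; ties break to the lexicographically
    smaller candidate id). Mapped SNPs are proxies, excluded from
    independent analysis."""
    mapping: dict[str, tuple[str, float]] = {}
    for snp in other_snps:
        best: tuple[float, str] | None = None
        for cand in candidate_ivs:
            r2 = ld_r2(genotypes[snp], genotypes[cand], method=method)
            if r2 >= r2_threshold:
                key = (-r2, cand)  # max r2, then lowest id
                if best is None or key < best:
                    best = key
        if best is not None:
            mapping[snp] = (best[1], -best[0])
    return mapping


def snp_exposure_assoc(
    df: pd.DataFrame,
    dosages,
    snp: str,
    exposure: str = "log_total_25ohd",
    covariates=("age", "bmi", "season"),
) -> RegressionResult:
    """Additive per-allele association of one SNP with the log exposure,
    adjusted for the standard covariates.

    ``dosages`` must be aligned row-for-row with ``df``.
    """
    x = _clean(dosages)
    if x.size != len(df):
        raise ValueError("dosages not aligned with cohort rows")
    merged = df.copy()
    merged[snp] = x
    return ols_adjusted(merged, exposure, snp, covariates=covariates, label=f"{exposure} ~ {snp}")


def iv_validity_screen(
    df: pd.DataFrame,
    genotypes: pd.DataFrame,
    ivs,
    confounders=("age", "bmi", "ca", "p", "cr", "bun"),
    outcomes=("bmd_l1l4", "bmd_fn", "bmd_th", "log_pth", "log_p1np"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen each candidate instrument against confounders and outcomes.

    Each variable is regressed on each IV dosage (additive coding, no
    covariates); p-values are FDR-corrected across the whole screen (one
    family). An IV passes when none of its associations survives at
    ``alpha``. Returns one row per (snp, variable) plus metadata columns.
    """
    if len(genotypes) != len(df):
        raise ValueError("genotype rows not aligned with cohort rows")
    rows = []
    for snp in ivs:
        merged = df.copy()
        merged[snp] = genotypes[snp].to_numpy()
        for var in list(confounders) + list(outcomes):
            res = ols_adjusted(merged, var, snp, covariates=(), label=f"{var} ~ {snp}")
            rows.append(
                {
                    "snp_id": snp,
                    "variable": var,
                    "kind": "confounder" if var in confounders else "outcome",
                    "beta": res.beta,
                    "p": res.p,
                    "n": res.n_used,
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_bh(table["p"].to_numpy())
    table["flagged"] = table["p_fdr"] < alpha
    table.attrs["alpha"] = alpha
    table.attrs["iv_pass"] = {
        snp: bool(~table.loc[table["snp_id"] == snp, "flagged"].any()) for snp in ivs
    }
    return table


def read_dosage_tsv(path) -> pd.DataFrame:
    """Read a subjects-by-SNPs dosage TSV (first column = subject id)."""
    g = pd.read_csv(path, sep="\t", index_col=0)
    for col in g.columns:
        _clean(g[col])
    return g


def read_vcf_dosages(path, effect_alleles: dict[str, str]) -> pd.DataFrame:
    """Dosage matrix from a VCF, oriented to configured effect alleles.

    ``effect_alleles`` maps variant id -> effect (vitamin-D-lowering)
    allele base; sites whose REF/ALT do not include that base raise (no
    strand flipping is inferred). Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = vcf.samples
    data = {}
    for variant in vcf:
        vid = variant.ID
        if vid not in effect_alleles:
            continue
        eff = effect_alleles[vid]
        alt = variant.ALT[0] if variant.ALT else None
        # gt_types counts ALT alleles; flip when the effect allele is REF
        alt_counts = np.array(
            [sum(1 for a in gt[:2] if a == 1) if -1 not in gt[:2] else np.nan
             for gt in variant.genotypes],
            dtype=float,
        )
        if eff == alt:
            data[vid] = alt_counts
        elif eff == variant.REF:
            data[vid] = 2.0 - alt_counts
        else:
            raise ValueError(
                f"{vid}: configured effect allele {eff!r} is neither REF "
                f"({variant.REF!r}) nor ALT ({alt!r})"
            )
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject"))
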