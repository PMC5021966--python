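"""Synthetic cohort generator.

Produces genotype and phenotype tables with the statistical structure the
downstream causal analysis assumes: genotypes in Hardy-Weinberg equilibrium
(optionally in LD pairs built from two-locus haplotypes), weak per-allele
effects on log 25OHD, a single latent standard-normal confounder U acting on
both the exposure and every outcome, and a configurable causal effect of
log 25OHD on each outcome. U and the generating parameters are emitted in a
truth sidecar that the analysis modules never read.

All randomness flows from one root seed through named substreams
("genotypes", "phenotypes", "exclusions") so each stage regenerates
independently and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .preprocess import season_of

__all__ = [
    "SyntheticCohort",
    "generate_genotypes",
    "generate_phenotypes",
    "inject_exclusions",
    "generate_cohort",
    "max_ld_r2",
]

_STREAMS = {"genotypes": 0, "phenotypes": 1, "exclusions": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def max_ld_r2(p_a: float, p_b: float) -> float:
    """Largest attainable r^2 between two loci with effect-allele freqs p_a, p_b.

    For positively associated effect alleles, D is capped at
    min(p_a (1-p_b), p_b (1-p_a)); r^2 = D^2 / (p_a q_a p_b q_b).
    """
    qa, qb = 1.0 - p_a, 1.0 - p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return 0.0
    d_max = min(p_a * qb, p_b * qa)
    return d_max**2 / (p_a * qa * p_b * qb)


def _ld_pair_dosages(
    rng: np.random.Generator, n: int, p_a: float, p_b: float, r2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample dosages for two loci from two-locus haplotypes at target r^2."""
    qa, qb = 1.0 - p_a, 1.0 - p_b
    r2_cap = max_ld_r2(p_a, p_b)
    if r2 > r2_cap + 1e-12:
        raise ValueError(
            f"target r2={r2} infeasible for effect-allele frequencies "
            f"({p_a}, {p_b}); maximum attainable r2 is {r2_cap:.6f}"
        )
    d = np.sqrt(r2 * p_a * qa * p_b * qb)
    hap = np.array(
        [
            qa * qb + d,   # (0, 0)
            qa * p_b - d,  # (0, 1)
            p_a * qb - d,  # (1, 0)
            p_a * p_b + d, # (1, 1)
        ]
    )
    hap = np.clip(hap, 0.0, None)
    hap = hap / hap.sum()
    draws = rng.choice(4, size=(n, 2), p=hap)
    dos_a = (draws >= 2).sum(axis=1)
    dos_b = (draws % 2).sum(axis=1)
    return dos_a, dos_b


def generate_genotypes(config: SyntheticConfig) -> pd.DataFrame:
    """Subject x SNP dosage matrix (effect-allele counts in {0, 1, 2}).

    Independent loci are drawn as Binomial(2, maf) per subject, which is
    exactly HWE; LD pairs are drawn jointly from two-locus haplotype
    frequencies implying the target r^2. Missing dosages (NaN) are injected
    at ``genotype_missing_rate`` if nonzero.
    """
    config.validate()
    rng = _rng(config.seed, "genotypes")
    n = config.n_subjects
    cols: dict[str, np.ndarray] = {}
    spec_by_id = {s.snp_id: s for s in config.snp_specs}
    for spec in config.snp_specs:
        if spec.ld_partner is None:
            if spec.snp_id not in cols:
                cols[spec.snp_id] = rng.binomial(2, spec.maf, size=n).astype(float)
        else:
            partner = spec_by_id[spec.ld_partner]
            dos_p, dos_s = _ld_pair_dosages(rng, n, partner.maf, spec.maf, spec.ld_r2)
            # the partner's column is replaced by the jointly drawn one so the
            # pair is internally consistent; partner must precede its proxy
            cols[partner.snp_id] = dos_p.astype(float)
            cols[spec.snp_id] = dos_s.astype(float)
    # preserve spec order
    g = pd.DataFrame(
        {s.snp_id: cols[s.snp_id] for s in config.snp_specs},
        index=pd.RangeIndex(n, name="subject"),
    )
    if config.genotype_missing_rate > 0:
        mask = rng.random(g.shape) < config.genotype_missing_rate
        g = g.mask(mask)
    return g


@dataclass
class SyntheticCohort:
    """Bundle of generated tables: phenotypes, genotypes, and truth sidecar."""

    cohort: pd.DataFrame
    genotypes: pd.DataFrame
    truth: pd.DataFrame


def generate_phenotypes(genotypes: pd.DataFrame, config: SyntheticConfig) -> SyntheticCohort:
    """Phenotype table given a dosage matrix.

    Exposure: log 25OHD = baseline + sum_j beta_j g_j + c_e U + eps.
    Each outcome (modelled scale): loc + causal * (log25OHD - baseline)
    + confounder_slope * U + covariate terms + noise; lognormal outcomes are
    exponentiated. Missing dosages contribute their expected value 2*maf to
    the exposure so the exposure stays defined for every subject.
    """
    config.validate()
    if len(genotypes) != config.n_subjects:
        raise ValueError(
            f"genotype rows ({len(genotypes)}) != n_subjects ({config.n_subjects})"
        )
    rng = _rng(config.seed, "phenotypes")
    n = config.n_subjects

    u = rng.standard_normal(n)
    genetic = np.zeros(n)
    for spec in config.snp_specs:
        if spec.effect == 0.0:
            continue
        dos = genotypes[spec.snp_id].to_numpy(dtype=float)
        dos = np.where(np.isnan(dos), 2.0 * spec.maf, dos)
        genetic += spec.effect * (dos - 2.0 * spec.maf)  # centred => baseline is the mean
    log_d = (
        config.baseline_log25ohd_mean
        + genetic
        + config.confounder_effect_exposure * u
        + rng.normal(0.0, config.exposure_noise_sd, n)
    )

    age = rng.normal(config.age_mean, config.age_sd, n)
    height = rng.normal(config.height_mean, config.height_sd, n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    weight = bmi * (height / 100.0) ** 2
    if config.season_month_probs is None:
        month = rng.integers(1, 13, size=n)
    else:
        month = rng.choice(np.arange(1, 13), size=n, p=config.season_month_probs)
    dbp = np.exp(rng.normal(config.dbp_log_median, config.dbp_log_sd, n))
    albumin = np.clip(rng.normal(config.albumin_mean, config.albumin_sd, n), 20.0, None)

    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
            "draw_month": month,
            "season": [season_of(m) for m in month],
            "total_25ohd": np.exp(log_d),
            "dbp": dbp,
            "albumin": albumin,
        }
    )
    for name, mean, sd in config.lab_specs:
        df[name] = rng.normal(mean, sd, n)

    for spec in config.outcomes:
        noise_sd = spec.noise_sd if spec.noise_sd is not None else spec.scale
        y = (
            spec.loc
            + spec.causal_effect * (log_d - config.baseline_log25ohd_mean)
            + spec.confounder_slope * u
            + spec.age_slope * (age - config.age_mean)
            + spec.bmi_slope * (bmi - config.bmi_mean)
            + rng.normal(0.0, noise_sd, n)
        )
        df[spec.name] = np.exp(y) if spec.family == "lognormal" else y

    df["excl_disease_medication"] = False
    df["excl_abnormal_lab"] = False

    truth = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "confounder_u": u,
            "log_25ohd_true": log_d,
        }
    )
    for spec in config.outcomes:
        truth[f"causal_effect_{spec.name}"] = spec.causal_effect
    return SyntheticCohort(cohort=df, genotypes=genotypes, truth=truth)


def inject_exclusions(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Set the two exclusion flags.

    Stage 1 (disease/medication) is drawn from everyone; stage 2 (abnormal
    labs) only from stage-1 survivors, so the flags are disjoint. In
    exact-count mode (``exclusion_counts``) the stated numbers of subjects
    are flagged without replacement; otherwise independent Bernoulli draws
    at ``exclusion_rates``.
    """
    config.validate()
    rng = _rng(config.seed, "exclusions")
    df = cohort.copy()
    n = len(df)
    stage1 = np.zeros(n, dtype=bool)
    stage2 = np.zeros(n, dtype=bool)
    if config.exclusion_counts is not None:
        k1, k2 = config.exclusion_counts
        if k1 + k2 > n:
            raise ValueError("exclusion counts exceed cohort size")
        idx1 = rng.choice(n, size=k1, replace=False)
        stage1[idx1] = True
        if k2 > 0:
            survivors = np.flatnonzero(~stage1)
            idx2 = rng.choice(survivors, size=k2, replace=False)
            stage2[idx2] = True
    else:
        r1, r2 = config.exclusion_rates
        stage1 = rng.random(n) < r1
        stage2 = (~stage1) & (rng.random(n) < r2)
    df["excl_disease_medication"] = stage1
    df["excl_abnormal_lab"] = stage2
    return df


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Genotypes, phenotypes and exclusion flags in one call."""
    g = generate_genotypes(config)
    bundle = generate_phenotypes(g, config)
    bundle.cohort = inject_exclusions(bundle.cohort, config)
    return bundle
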