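# Methods

## Scope and design

`vitdmr` implements a one-sample, individual-level Mendelian randomization
(MR) analysis of serum 25-hydroxyvitamin D (25OHD, exposure) against bone
mineral density (lumbar spine L1-L4, femoral neck, total hip; g/cm²) and
bone-metabolism markers (PTH, P1NP, Beta-CTX), together with every
supporting stage: cohort preprocessing, free/bioavailable 25OHD
computation, SNP quality control, the observational OLS stage, and a
synthetic-cohort generator that supplies ground truth. The generator is
first-class, tested code: all statistical guarantees of the causal stage
(consistency under confounding, CI coverage, Hausman power) are verified
against it.

## Synthetic cohort generator

**Genotypes.** Each locus is drawn per subject as Binomial(2, p) in the
frequency p of the effect allele — exactly Hardy-Weinberg proportions.
Loci declared as LD pairs are drawn jointly from two-locus haplotype
frequencies h = (q_aq_b+D, q_ap_b−D, p_aq_b−D, p_ap_b+D) with
D = √(r²·p_aq_ap_bq_b); a target r² above the attainable maximum
D²_max/(p_aq_ap_bq_b), D_max = min(p_aq_b, p_bq_a), raises an error naming
the bound. Dosages are counts of the vitamin-D-**lowering** allele, the
orientation the analysis assumes; the MR battery warns
(`OrientationWarning`) if the allele score turns out positively associated
with the exposure. The default panel is ten vitamin-D-pathway SNPs: four
instruments (allele frequencies 0.338, 0.462, 0.379, 0.162), three proxies
at r² = 0.95/0.99/0.99 to them, and three further variants with small or
null effects.

**Exposure.** log 25OHD = μ + Σ_j β_j(g_j − 2p_j) + c_e·U + ε, with
U ~ N(0,1) a single latent confounder shared with all outcomes and
ε ~ N(0, σ_x). Defaults: μ = log 18.3 (median 18.3 ng/mL), σ_x = 0.395 and
c_e = 0.15, giving total SD(log 25OHD) ≈ 0.43 — the value implied by an
IQR of 13.3-23.8 ng/mL. Per-allele effects (−0.068, −0.0555, −0.057,
−0.070) give each instrument an R² of 0.7-1.1% of exposure variance, the
weak-instrument regime this analysis lives in; the lead *GC* SNP sits at
≈1.1% (F ≈ 20 at n = 1,824).

**Outcomes.** On the modelled scale (natural for BMD, log for the
markers): y = loc + β_c·(log25OHD − μ) + c_o·U + covariate terms + noise,
exponentiated for log-normal markers. Locations and scales reproduce the
cohort descriptives (e.g. BMD L1-L4 0.877 ± 0.141 g/cm²; PTH median 40.7
pg/mL with log-scale SD = IQR width/1.349 ≈ 0.36). The confounder slope is
+|c_o| for BMD and −|c_o| for turnover markers (low vitamin D status
travels with low BMD and high PTH observationally), and the residual SD is
shrunk so the total SD stays at the descriptive value. A small age slope
on BMD (−0.004 g/cm²/yr) makes covariate adjustment non-trivial; age, BMI
and season are generated independently of exposure and outcome, so the
population OLS slope has the closed form β_c + c_o·c_e/Var(x) — the
"analytic omitted-variable slope" the tests check against.

**Scenarios.** Two named calibrations, both with causal effect zero by
default:

* `paper_like_config` — c_e = 0.15, c_o = 0.35·SD_y. OLS bias ≈ 0.28
  SD_y per log-unit (0.040 g/cm² for BMD L1-L4), a decisively nonzero
  observational association at n ≈ 1,800 but mild endogeneity. Used for
  parameter-recovery and coverage studies.
* `confounded_null_config` — c_e = 0.40 (σ_x shrunk to 0.136 to keep
  SD(log 25OHD) ≈ 0.43), c_o = 0.93·SD_y, observational correlation
  ρ ≈ 0.86. Chosen from the power algebra of the Hausman statistic: its
  noncentrality is ≈ ρ²·n·R²_instrument, so with R² in the 0.011-0.035
  range this puts per-test power at ≈95-100%, making the qualitative
  headline (observational significant / MR null / Hausman significant)
  statistically stable. These slopes were fixed from this calculation, not
  adjusted afterwards.

**Exclusions.** Stage 1 (disease/medication) is drawn from all subjects,
stage 2 (abnormal labs) only from stage-1 survivors, so flags are
disjoint. Bernoulli mode uses rates (default 0.0785, 0.0167); exact-count
mode flags stated numbers without replacement and exists to reproduce the
2,013 → 158 → 31 → 1,824 cascade deterministically.

**Randomness.** One root seed feeds named substreams (genotypes,
phenotypes, exclusions) via `SeedSequence(seed, spawn_key=...)`; each
module regenerates independently and byte-identically. The latent U and
generating parameters are written to a truth sidecar that no analysis
module reads.

**What the generator does not emulate:** genome-wide data, population
structure, assay measurement error beyond additive noise, covariate
correlations (age × BMI × season are independent), imputation uncertainty,
or real-data effect heterogeneity across instruments. A visible
consequence of the last point: with all four instruments genuinely
informative, the allele-score models' first-stage R² (~3.5%) exceeds the
single-SNP R² (~1.1%), whereas real cohorts can show the reverse when some
instruments carry little in-sample signal. Passing tests therefore
certify the estimators' statistical behaviour under the assumed causal
structure, not robustness to violations of it.

## Preprocessing

* **Exclusion cascade:** two sequential stages; percentages are of the
  enrolled total. Reported percentages follow the clinical-table display
  convention of computing to two decimals and displaying one (half away
  from zero at each step), so 158/2013 → 7.85 → 7.9%.
* **Extreme values:** single-pass |z| > 3.5 rule with mean and SD computed
  once from all non-missing values; trimmed points become missing for the
  affected variable only (per-analysis, not subject-level, removal).
  Skewed variables are trimmed on their log scale, after transformation.
  A zero-variance vector keeps everything; missing values are never
  counted as extreme.
* **Log transform:** natural log of 25OHD, PTH, Beta-CTX and P1NP (and of
  the computed free/bioavailable fractions for their association battery);
  originals retained; non-positive values are a hard error naming
  subjects.
* **Normality rule:** |sample skewness| > 1 selects the median (Q1, Q3)
  branch in descriptives and the Kruskal-Wallis branch in group tests;
  shared package-wide so the two stages cannot disagree. Quartiles use
  linear interpolation between order statistics.
* **Season:** blood-draw month mapped by Northern-Hemisphere
  meteorological seasons (Dec-Feb winter, etc.), overridable in config;
  months are drawn uniformly unless probabilities are configured. Season
  enters models as winter-referenced dummies.

## Free and bioavailable 25OHD

Mass balance over the two carriers, all in mol/L:
T = F(1 + k_alb·[Alb]) + [DBP]·k_dbp·F/(1 + k_dbp·F). The **linear**
solver assumes trace ligand (denominator 1), F = T/(1 + k_alb[Alb] +
k_dbp[DBP]); the **exact** solver keeps DBP saturable and takes the unique
non-negative root of the resulting quadratic. At physiologic
concentrations the ligand/capacity ratio is ~2%, which bounds the linear
solver's relative error; the linear form is the default as the common
practice of the free-vitamin-D literature. Defaults (configurable, since
any given study may use others): k_dbp = 7×10⁸ L/mol, k_alb = 6×10⁵
L/mol, MW 58,000 (DBP), 66,430 (albumin), 400.6 (25OHD). Outputs: free in
pg/mL, bioavailable (free + albumin-bound) in ng/mL. Mass balance holds to
<10⁻⁹ relative for the exact solver by construction of the root.

## Genetics QC

MAF from dosage means; Hardy-Weinberg via the plain 1-df χ² against
expected proportions at the sample allele frequency (no continuity
correction or exact test; monomorphic loci are defined to p = 1 with a
warning, since a fixed locus carries no genotyping-error information). QC
pass requires genotyping rate > 0.90 **and** HWE p > 0.05, both strict.
LD r² defaults to the composite (squared Pearson dosage correlation)
estimator because genotypes are unphased; an EM haplotype-frequency
estimator under HWE is provided as a cross-check and agrees within 0.02 on
HWE data at n ≥ 5,000. Proxy selection maps any non-candidate SNP with
r² ≥ 0.8 to its best candidate (ties to the lexicographically smaller id).
The validity screen regresses each potential confounder (age, BMI, Ca, P,
Cr, BUN) and each outcome on each IV, FDR-corrects across the whole screen
as one family, and passes an IV only if nothing survives.

## Estimation

**Observational stage:** OLS of each outcome on log exposure with age, BMI
and season dummies (statsmodels); unadjusted and adjusted estimates
reported, adjusted p-values FDR-corrected within the battery. One BH
family per results battery (observational; per-SNP exposure; validity
screen; Hausman), mirroring per-table correction.

**First stage:** log exposure on allele score + covariates; incremental R²
is the gain over covariates alone, the partial F is the squared t of the
score term. The closed-form conversion F = (n−1−k)/k·r²/(1−r²) is also
reported; the two agree to ~2 dp when covariates are nearly orthogonal to
the score and the (small) discrepancy is visible in the diagnostics table
rather than hidden. Relative 2SLS/OLS bias is approximated by 1/F, with
F ≤ 10 flagged weak. (At F = 20.26 the 1/F value is 0.0494, which prints
as 0.049; reports that quote 0.050 for this F have rounded upstream.)

**2SLS:** computed both as the control-function regression (outcome on
fitted exposure, covariates, first-stage residual) and as the canonical
matrix estimator; the exposure coefficients are algebraically identical
and cross-asserted to 10⁻⁸ on every call (the check is skipped in the
degenerate self-instrumenting case where the residual column vanishes and
2SLS coincides with OLS). Reported SE/p use the matrix form with
homoskedastic variance from the structural residual y − Xβ̂ and a t
reference with n − k df; a sandwich variant is deliberately not the
default. Subjects missing any instrument dosage are dropped listwise for
all three models so n is constant within a battery.

**Hausman:** (β_IV − β_OLS)²/(se²_IV − se²_OLS) on the same subjects,
χ²₁; a non-positive variance difference returns status "degenerate" with
no p-value rather than a negative statistic. Battery p-values are
FDR-adjusted together.

**Model variants:** single lead-SNP instrument (lead SNP from config, not
re-derived in-sample), unweighted allele score, weighted allele score with
external per-allele weights from config — in-sample re-estimated weights
would reintroduce winner's-curse bias, so none are computed.

## Verification strategy and problem sizes

The replicated studies run at the analysed cohort size (n = 1,824):
parameter recovery and CI coverage use 500 replicates each (Monte-Carlo SE
of the mean 2SLS estimate ≈ 0.004, small enough to resolve the analytic
OLS bias of 0.040); HWE calibration uses 1,000 loci of n = 500; the
headline contrast pools 12 replicate cohorts (60 observational, 180 2SLS
and 144 Hausman tests), with thresholds (≥0.99, <0.25, >0.75) placed many
binomial SDs from the analytically expected fractions (~1.0, ~0.06-0.15,
~0.95-1.0). Those sizes keep the full suite under a minute of simulation
time while leaving the checks statistically decisive.

## Known limitations

Single latent confounder; linear, homogeneous causal effects (no
nonlinearity across the physiologic range, no effect modification); no
two-sample or summary-statistic MR, no MR-Egger/weighted-median
pleiotropy-robust estimators; no population-stratification correction; no
genotype imputation; no DBP-genotype-specific binding affinities. The
Hausman test's power collapses when instruments are weak (its
noncentrality scales with n·R²·ρ²), so a non-significant Hausman test on
weak instruments is not evidence of exogeneity.
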