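"""SNP quality control: allele frequencies, HWE, genotyping rate, LD and
the instrument-validity screen."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vitdmr.config import SnpSpec, SyntheticConfig
from vitdmr.qc import (
    allele_freq,
    genotype_counts,
    genotyping_rate,
    hwe_chisq,
    iv_validity_screen,
    ld_r2,
    select_proxies,
    snp_exposure_assoc,
    snp_qc_table,
)
from vitdmr.synthetic import generate_genotypes, generate_phenotypes


def _dosages(n0, n1, n2):
    return np.repeat([0.0, 1.0, 2.0], [n0, n1, n2])


class TestAlleleFreq:
    def test_all_reference_is_zero(self):
        assert allele_freq(np.zeros(10)) == (0.0, 0.0)

    def test_one_of_each_genotype(self):
        f, maf = allele_freq(np.array([0.0, 1.0, 2.0]))
        assert (f, maf) == (0.5, 0.5)

    def test_hand_counted_example(self):
        # (AA, Aa, aa) = (45, 40, 15): f = (40 + 30)/200 = 0.35
        f, maf = allele_freq(_dosages(45, 40, 15))
        assert maf == pytest.approx(0.35)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            allele_freq(np.full(5, np.nan))

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            allele_freq(np.array([0.0, 3.0]))


class TestHweChisq:
    def test_exact_hwe_proportions_give_zero(self):
        chi2, p = hwe_chisq((25, 50, 25))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_summed_example(self):
        # counts (10,10,10): p=0.5, expected (7.5,15,7.5), chi2 = 10/3
        chi2, _ = hwe_chisq((10, 10, 10))
        assert chi2 == pytest.approx(10.0 / 3.0)

    def test_monomorphic_defined_as_one_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            chi2, p = hwe_chisq((30, 0, 0))
        assert p == 1.0

    def test_allele_frequency_consistent_with_allele_freq(self):
        dos = _dosages(45, 40, 15)
        f, _ = allele_freq(dos)
        n0, n1, n2 = genotype_counts(dos)
        assert (n1 + 2 * n2) / (2 * (n0 + n1 + n2)) == pytest.approx(f)


class TestGenotypingRateAndQcTable:
    def test_no_missing_is_one(self):
        assert genotyping_rate(np.zeros(10)) == 1.0

    def test_boundary_rate_fails_strict_threshold(self):
        col = np.append(_dosages(45, 40, 5), np.full(10, np.nan))
        assert genotyping_rate(col) == pytest.approx(0.90)
        tab = snp_qc_table(pd.DataFrame({"s": col}))
        assert not tab["qc_pass"].iloc[0]  # 0.90 is not > 0.90

    def test_good_rate_but_hwe_failure_fails_qc(self):
        # gross heterozygote deficit: far off HWE
        col = _dosages(60, 0, 40)
        tab = snp_qc_table(pd.DataFrame({"s": col}))
        assert tab["hwe_p"].iloc[0] < 0.05
        assert tab["genotyping_rate"].iloc[0] == 1.0
        assert not tab["qc_pass"].iloc[0]


class TestLd:
    def test_identical_columns_are_r2_one(self):
        col = _dosages(30, 40, 30)
        assert ld_r2(col, col) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        cfg = SyntheticConfig(
            n_subjects=100_000,
            snp_specs=(SnpSpec("a", 0.3), SnpSpec("b", 0.4)),
            outcomes=(), seed=8,
        )
        g = generate_genotypes(cfg)
        assert ld_r2(g["a"], g["b"]) < 0.001

    def test_composite_recovers_generator_target(self):
        cfg = SyntheticConfig(
            n_subjects=10_000,
            snp_specs=(SnpSpec("a", 0.338), SnpSpec("b", 0.333, ld_partner="a", ld_r2=0.95)),
            outcomes=(), seed=2,
        )
        g = generate_genotypes(cfg)
        assert ld_r2(g["a"], g["b"]) == pytest.approx(0.95, abs=0.02)

    def test_em_and_composite_agree_on_hwe_data(self):
        cfg = SyntheticConfig(
            n_subjects=5_000,
            snp_specs=(SnpSpec("a", 0.35), SnpSpec("b", 0.25, ld_partner="a", ld_r2=0.5)),
            outcomes=(), seed=6,
        )
        g = generate_genotypes(cfg)
        comp = ld_r2(g["a"], g["b"], method="composite")
        em = ld_r2(g["a"], g["b"], method="em")
        assert abs(comp - em) < 0.02

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ld_r2(np.zeros(10), _dosages(3, 4, 3))


class TestProxySelection:
    def test_mapping_threshold_and_tie_break(self):
        col = _dosages(30, 40, 30)
        rng = np.random.default_rng(0)
        indep = rng.binomial(2, 0.3, 100).astype(float)
        g = pd.DataFrame({"cand_a": col, "cand_b": col, "proxy": col, "other": indep})
        mapping = select_proxies(["cand_a", "cand_b"], ["proxy", "other"], g, r2_threshold=0.8)
        # tie at r2 = 1.0 resolves to the lexicographically smaller candidate
        assert mapping["proxy"][0] == "cand_a"
        assert mapping["proxy"][1] == pytest.approx(1.0)
        assert "other" not in mapping


class TestSnpExposureAssoc:
    def _frame(self, n, rng):
        return pd.DataFrame(
            {
                "age": rng.normal(65, 9, n),
                "bmi": rng.normal(23, 3, n),
                "season": rng.choice(["winter", "spring", "summer", "autumn"], n),
            }
        )

    def test_exact_linear_relation_recovered_to_machine_precision(self):
        rng = np.random.default_rng(3)
        n = 200
        df = self._frame(n, rng)
        dos = rng.binomial(2, 0.3, n).astype(float)
        df["log_total_25ohd"] = 0.5 * dos
        res = snp_exposure_assoc(df, dos, "s")
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_generator_effect_size_recovered_within_ci(self):
        cfg = SyntheticConfig(
            n_subjects=20_000,
            snp_specs=(SnpSpec("a", 0.409, -0.017),),
            outcomes=(), seed=4,
        )
        g = generate_genotypes(cfg)
        bundle = generate_phenotypes(g, cfg)
        df = bundle.cohort.copy()
        df["log_total_25ohd"] = np.log(df["total_25ohd"])
        res = snp_exposure_assoc(df, g["a"].to_numpy(), "a")
        assert res.ci_low <= -0.017 <= res.ci_high

    def test_null_association_centred_on_zero(self):
        rng = np.random.default_rng(9)
        n = 3000
        df = self._frame(n, rng)
        df["log_total_25ohd"] = rng.normal(2.9, 0.4, n)
        dos = rng.binomial(2, 0.3, n).astype(float)
        res = snp_exposure_assoc(df, dos, "s")
        assert abs(res.beta) < 4 * res.se


class TestValidityScreen:
    def test_null_design_passes_and_planted_pleiotropy_is_flagged(self):
        rng = np.random.default_rng(12)
        n = 2000
        g = pd.DataFrame(
            {"iv1": rng.binomial(2, 0.3, n).astype(float),
             "iv2": rng.binomial(2, 0.4, n).astype(float)}
        )
        df = pd.DataFrame(
            {
                "age": rng.normal(65, 9, n),
                "bmi": rng.normal(23, 3, n),
                "ca": rng.normal(2.33, 0.1, n),
                "bmd": rng.normal(0.88, 0.14, n),
                # iv2 wired straight into this outcome: direct pleiotropy
                "pleio": 0.1 * g["iv2"] + rng.normal(0, 0.14, n),
            }
        )
        tab = iv_validity_screen(
            df, g, ["iv1", "iv2"],
            confounders=("age", "bmi", "ca"),
            outcomes=("bmd", "pleio"),
            alpha=0.05,
        )
        assert tab.attrs["alpha"] == 0.05
        assert tab.attrs["iv_pass"]["iv1"]
        assert not tab.attrs["iv_pass"]["iv2"]
        flagged = tab.loc[tab["flagged"]]
        assert set(zip(flagged["snp_id"], flagged["variable"])) == {("iv2", "pleio")}
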