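"""Allele scores, 2SLS, weak-instrument diagnostics and the Hausman test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitdmr.assoc import ols_adjusted
from vitdmr.config import confounded_null_config, paper_like_config
from vitdmr.mr import (
    HausmanResult,
    InstrumentSet,
    MRResult,
    OrientationWarning,
    build_allele_score,
    f_from_r2,
    first_stage,
    hausman,
    is_weak,
    relative_bias,
    run_mr_battery,
    sample_size_inflation,
    tsls,
)
from vitdmr.preprocess import log_transform_skewed
from vitdmr.synthetic import generate_genotypes, generate_phenotypes


def _frame(rng, n, x=None):
    df = pd.DataFrame(
        {
            "age": rng.normal(65, 9, n),
            "bmi": rng.normal(23, 3, n),
            "season": rng.choice(["winter", "spring", "summer", "autumn"], n),
        }
    )
    if x is not None:
        df["x"] = x
    return df


class TestAlleleScore:
    G = pd.DataFrame(
        {"a": [2.0, 0.0, 1.0], "b": [1.0, 0.0, 1.0], "c": [0.0, 0.0, 2.0], "d": [1.0, 0.0, 0.0]}
    )

    def test_all_zero_dosages_score_zero(self):
        inst = InstrumentSet(("a", "b"), "unweighted")
        assert build_allele_score(self.G.iloc[[1]], inst).iloc[0] == 0.0

    def test_unweighted_counts_alleles(self):
        inst = InstrumentSet(("a", "b", "c", "d"), "unweighted")
        assert build_allele_score(self.G, inst).iloc[0] == 4.0

    def test_weighted_sum(self):
        inst = InstrumentSet(("a", "b", "c", "d"), "weighted", (0.3, 0.2, 0.1, 0.4))
        assert build_allele_score(self.G, inst).iloc[0] == pytest.approx(1.2)

    def test_missing_dosage_propagates_nan(self):
        g = self.G.copy()
        g.loc[0, "a"] = np.nan
        inst = InstrumentSet(("a", "b"), "unweighted")
        score = build_allele_score(g, inst)
        assert np.isnan(score.iloc[0]) and not np.isnan(score.iloc[1])

    def test_unknown_snp_and_weight_mismatch_error(self):
        with pytest.raises(KeyError):
            build_allele_score(self.G, InstrumentSet(("zz",), "single"))
        with pytest.raises(ValueError):
            InstrumentSet(("a", "b"), "weighted", (0.1,))
        with pytest.raises(ValueError):
            InstrumentSet(("a", "b"), "single")


class TestInstrumentStrength:
    def test_f_conversion_matches_published_diagnostics(self):
        assert round(f_from_r2(0.011, 1824, 1), 2) == 20.26
        assert round(f_from_r2(0.007, 1824, 1), 2) == 12.84
        assert f_from_r2(0.0, 100, 1) == 0.0

    def test_f_conversion_domain(self):
        with pytest.raises(ValueError):
            f_from_r2(1.0, 100, 1)
        with pytest.raises(ValueError):
            f_from_r2(0.1, 3, 2)

    def test_relative_bias_values_and_weak_flag(self):
        assert round(relative_bias(12.84), 3) == 0.078
        assert relative_bias(10.0) == pytest.approx(0.1)
        assert is_weak(10.0) and not is_weak(10.01)
        fs = np.array([5.0, 20.0, 100.0, 1000.0])
        rb = np.array([relative_bias(f) for f in fs])
        assert np.all(np.diff(rb) < 0)
        with pytest.raises(ValueError):
            relative_bias(0.0)

    def test_sample_size_inflation_identity(self):
        assert sample_size_inflation(0.8) == pytest.approx(0.5625)

    def test_first_stage_extremes(self):
        rng = np.random.default_rng(0)
        n = 500
        score = rng.binomial(2, 0.3, n).astype(float)
        w = np.column_stack([np.ones(n), rng.normal(size=n)])
        fs = first_stage(score.copy(), score, w)
        # exact fit: residuals vanish; the R2 gain is 1 minus the small
        # chance R2 of the covariates alone
        assert np.allclose(fs.residuals, 0.0, atol=1e-10)
        assert fs.incremental_r2 == pytest.approx(1.0, abs=0.02)
        x = rng.normal(size=n)
        fs0 = first_stage(x, score, w)
        assert fs0.incremental_r2 < 0.02
        with pytest.raises(ValueError):
            first_stage(x, np.ones(n), w)


class TestTsls:
    def test_self_instrumenting_equals_ols(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.normal(2.9, 0.4, n)
        df = _frame(rng, n, x)
        df["y"] = 0.3 * x + rng.normal(0, 0.2, n)
        res = tsls(df, "y", "x", x)
        ols = ols_adjusted(df, "y", "x")
        assert res.beta == pytest.approx(ols.beta, abs=1e-10)

    def test_eight_row_fixture_matches_matrix_oracle(self):
        y = np.array([1.2, 0.7, 1.9, 2.1, 1.4, 2.8, 0.3, 1.6])
        x = np.array([0.5, 0.1, 1.0, 1.2, 0.8, 1.5, -0.2, 0.9])
        z = np.array([1.0, 0.0, 2.0, 2.0, 1.0, 2.0, 0.0, 1.0])
        c = np.array([0.3, -0.5, 0.8, 0.1, 0.0, 1.1, -0.9, 0.4])
        df = pd.DataFrame({"y": y, "x": x, "c": c})
        res = tsls(df, "y", "x", z, covariates=("c",))
        X = np.column_stack([x, np.ones(8), c])
        Z = np.column_stack([z, np.ones(8), c])
        beta = np.linalg.solve(Z.T @ X, Z.T @ y)  # just-identified 2SLS
        assert res.beta == pytest.approx(beta[0], abs=1e-10)

    def test_consistent_under_confounding_where_ols_is_not(self):
        rng = np.random.default_rng(2)
        n = 60_000
        u = rng.standard_normal(n)
        z = rng.binomial(2, 0.35, n).astype(float)
        x = 2.9 - 0.3 * z + 0.3 * u + rng.normal(0, 0.3, n)
        df = _frame(rng, n, x)
        df["y"] = 0.0 * x + 0.4 * u + rng.normal(0, 0.5, n)
        res = tsls(df, "y", "x", z)
        ols = ols_adjusted(df, "y", "x")
        assert abs(res.beta) < 3.5 * res.se
        assert ols.beta > 10 * ols.se  # decisively biased away from 0

    def test_zero_variance_score_errors(self):
        rng = np.random.default_rng(3)
        n = 50
        df = _frame(rng, n, rng.normal(size=n))
        df["y"] = rng.normal(size=n)
        with pytest.raises(ValueError):
            tsls(df, "y", "x", np.ones(n))


class TestHausman:
    def _ols(self, beta, se, n=100):
        from vitdmr.assoc import RegressionResult
        return RegressionResult(beta, se, beta - 2 * se, beta + 2 * se, 0.5, n, 0.1)

    def _iv(self, beta, se, n=100):
        return MRResult("single", "y", beta, se, beta - 2 * se, beta + 2 * se,
                        0.5, 0.01, 20.0, 20.0, 0.05, False, n)

    def test_equal_estimates_give_zero_statistic(self):
        h = hausman(self._ols(0.3, 0.01), self._iv(0.3, 0.05))
        assert h.stat == pytest.approx(0.0)
        assert h.p == pytest.approx(1.0)

    def test_plug_in_arithmetic(self):
        h = hausman(self._ols(0.047, 0.016), self._iv(-0.048, 0.056))
        expected = 0.095**2 / (0.056**2 - 0.016**2)
        assert h.stat == pytest.approx(expected)
        assert h.p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_degenerate_when_iv_variance_not_larger(self):
        h = hausman(self._ols(0.3, 0.06), self._iv(0.2, 0.05))
        assert h.status == "degenerate"
        assert h.p is None

    def test_mismatched_samples_error(self):
        with pytest.raises(ValueError):
            hausman(self._ols(0.3, 0.01, n=90), self._iv(0.2, 0.05, n=100))


class TestBattery:
    def test_fifteen_rows_and_determinism(self, small_bundle):
        bundle, _ = small_bundle
        df = log_transform_skewed(bundle.cohort)
        b1 = run_mr_battery(df, bundle.genotypes)
        b2 = run_mr_battery(df, bundle.genotypes)
        assert len(b1) == 15  # 5 outcomes x 3 models
        assert set(b1["model"]) == {"single", "unweighted", "weighted"}
        pd.testing.assert_frame_equal(b1, b2)

    def test_constant_n_within_battery_under_missingness(self, small_bundle):
        bundle, _ = small_bundle
        df = log_transform_skewed(bundle.cohort)
        g = bundle.genotypes.copy()
        g.iloc[:15, g.columns.get_loc("rs2282679")] = np.nan
        battery = run_mr_battery(df, g)
        assert battery["n"].nunique() == 1
        assert battery["n"].iloc[0] == len(df) - 15

    def test_orientation_warning_on_flipped_effect_alleles(self, small_bundle):
        bundle, _ = small_bundle
        df = log_transform_skewed(bundle.cohort)
        flipped = 2.0 - bundle.genotypes  # raising-allele coding
        with pytest.warns(OrientationWarning):
            run_mr_battery(df, flipped)

    def test_multi_instrument_score_shrinks_se_versus_single(self):
        """With every instrument informative, the weighted-score SE is
        smaller than the single-SNP SE on average across replicates."""
        ratios = []
        for seed in range(20):
            cfg = dataclasses.replace(
                paper_like_config(seed), n_subjects=1000, exclusion_rates=(0.0, 0.0)
            )
            g = generate_genotypes(cfg)
            bundle = generate_phenotypes(g, cfg)
            df = log_transform_skewed(bundle.cohort)
            battery = run_mr_battery(df, g, outcomes=("bmd_l1l4",))
            by_model = battery.set_index("model")["se"]
            ratios.append(by_model["weighted"] / by_model["single"])
        assert np.mean(ratios) < 1.0
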