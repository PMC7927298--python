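"""Linear models, Pearson-Filon z, multiple-testing correction."""

import numpy as np
import pytest

import csvdnet as cn
from csvdnet.exceptions import ValidationError
from csvdnet.stats import AnalysisPlan, adjust_pvalues


class TestLinearModel:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 30)
        fit = cn.fit_linear_model(2 * x, x)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictor(self):
        n = 40
        x = np.tile([1.0, -1.0], n // 2)
        y = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to x
        fit = cn.fit_linear_model(y, x)
        assert abs(fit.params["x"]) < 1e-9
        assert fit.pvalues["x"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        n, p = 200, 4
        x = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = x @ beta + rng.standard_normal(n)
        fit = cn.fit_linear_model(
            y, x[:, 0], covariates=x[:, 1:], covariate_names=["a", "b", "c"]
        )
        design = np.column_stack([np.ones(n), x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        got = [fit.params[k] for k in ["const", "x", "a", "b", "c"]]
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_simple_r_is_signed_sqrt_of_r_squared(self, rng):
        x = rng.standard_normal(100)
        y = -0.7 * x + rng.standard_normal(100)
        fit = cn.fit_linear_model(y, x)
        assert fit.r == pytest.approx(np.sign(fit.params["x"]) * np.sqrt(fit.r_squared), abs=1e-9)

    def test_collinear_design_named(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(ValidationError, match="dup"):
            cn.fit_linear_model(
                rng.standard_normal(50), x, covariates=2 * x[:, None], covariate_names=["dup"]
            )

    def test_missing_values_rejected(self):
        y = np.array([1.0, np.nan, 2.0] * 10)
        with pytest.raises(ValidationError):
            cn.fit_linear_model(y, np.arange(30.0))


class TestPearsonFilon:
    def test_equal_correlations_give_zero(self):
        comp = cn.pearson_filon_z(0.4, 0.4, 0.2, 100)
        assert comp.z == 0.0
        assert comp.p == 1.0

    def test_reported_cohort_comparison_significant(self):
        # pWMH vs dWMH correlation with normalised efficiency at n = 930
        comp = cn.pearson_filon_z(-0.39, -0.19, 0.5, 930)
        assert comp.p < 0.001
        assert comp.z < 0

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValidationError):
            cn.pearson_filon_z(1.0, 0.2, 0.1, 50)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            cn.pearson_filon_z(0.3, 0.1, 0.2, 5)

    def test_power_monotone_in_effect_size(self):
        zs = [abs(cn.pearson_filon_z(0.2 + d, 0.2, 0.3, 500).z) for d in (0.1, 0.25, 0.4)]
        assert zs[0] < zs[1] < zs[2]

    def test_variance_matches_bootstrap_oracle(self):
        # nonparametric bootstrap of r_jk - r_jh on one simulated dataset
        rng = np.random.default_rng(7)
        n = 400
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.45], [0.3, 0.45, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=n)
        r = np.corrcoef(x, rowvar=False)
        comp = cn.pearson_filon_z(r[0, 1], r[0, 2], r[1, 2], n)
        analytic_sd = (comp.r_jk - comp.r_jh) / comp.z  # sd of the difference
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            rb = np.corrcoef(x[idx], rowvar=False)
            diffs.append(rb[0, 1] - rb[0, 2])
        boot_sd = np.std(diffs, ddof=1)
        assert analytic_sd == pytest.approx(boot_sd, rel=0.15)


class TestAdjustPvalues:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.01]), [0.01])

    def test_bonferroni_multiplies_and_caps(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.5]), [0.03, 0.06, 1.0]
        )

    def test_bh_matches_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, size=15)

        def bh_oracle(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            prev = 1.0
            for rank_pos in range(m - 1, -1, -1):
                i = order[rank_pos]
                val = min(prev, pvals[i] * m / (rank_pos + 1))
                adj[i] = val
                prev = val
            return adj

        np.testing.assert_allclose(adjust_pvalues(p, method="bh"), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5])


class TestAssociationAnalysis:
    @staticmethod
    def null_cohort(n=300, seed=0):
        """Cohort where markers and parameters are independent."""
        rng = np.random.default_rng(seed)
        df = {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(45, 74, n),
            "sex": rng.integers(0, 2, n),
            "education_years": rng.normal(13, 3, n),
            "brain_volume_ml": rng.normal(1480, 100, n),
            "median_edge_weight": rng.normal(28, 3, n),
            "mmst": rng.normal(28, 1, n),
            "tmta_seconds": rng.lognormal(np.log(36), 0.2, n),
            "tmtb_seconds": rng.lognormal(np.log(79), 0.2, n),
        }
        for m in ["psmd", "log_wmh_load", "log_pwmh_load", "log_dwmh_load"]:
            df[m] = rng.standard_normal(n)
        for p in ["geff_norm", "clus_norm", "modularity_q", "swp"]:
            df[p] = rng.standard_normal(n)
        import pandas as pd

        return pd.DataFrame(df)

    def test_missing_column_named(self):
        df = self.null_cohort().drop(columns=["swp"])
        with pytest.raises(ValidationError, match="swp"):
            cn.run_association_analysis(df)

    def test_output_cardinality(self):
        res = cn.run_association_analysis(self.null_cohort())
        simple = res["associations"].query("model == 'simple' and term == predictor")
        assert len(simple) == 16  # 4 markers x 4 parameters
        assert len(res["comparisons"]) == 4
        cog_focal = res["cognition"].query("term == predictor")
        assert len(cog_focal) == 3 * 7 * 2  # outcomes x predictors x models

    def test_null_cohort_pvalues_roughly_uniform(self):
        # aggregate over several independent null cohorts
        ps = []
        for seed in range(4):
            res = cn.run_association_analysis(self.null_cohort(seed=seed))
            simple = res["associations"].query("model == 'simple' and term == predictor")
            ps.extend(simple["p"].tolist())
        frac = np.mean(np.asarray(ps) < 0.05)
        assert frac < 0.15  # 64 null tests; expect ~5% rejections

    def test_deterministic(self):
        df = self.null_cohort()
        a = cn.run_association_analysis(df)
        b = cn.run_association_analysis(df)
        for key in a:
            assert a[key].equals(b[key])
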