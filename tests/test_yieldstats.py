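"""Yield statistics: normality screening, abundance-weighted predictors,
regression summaries, and LOOCV aggregation against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from paddysma import combined_index, correlate, fit_linear, loocv_fit, \
    normality_test, pearson, rank_models
from paddysma.yieldstats import DegenerateInputError, significance_stars
from .oracles import loocv_oracle


class TestNormality:
    def test_normal_sample_agrees_with_reference_routine(self):
        x = np.random.default_rng(0).normal(size=100)
        assert normality_test(x) == pytest.approx(stats.shapiro(x).pvalue, abs=1e-6)

    def test_agrees_with_r_shapiro_test(self, tmp_path):
        # independent oracle: R's shapiro.test on the same sample
        import shutil, subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        x = np.random.default_rng(7).normal(size=50)
        script = tmp_path / "sw.R"
        script.write_text(
            "x <- c(%s)\ncat(sprintf('%%.10f', shapiro.test(x)$p.value))\n"
            % ",".join(f"{v:.12g}" for v in x))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        assert normality_test(x) == pytest.approx(float(out.stdout), abs=1e-6)

    def test_bimodal_sample_rejected_as_normal(self):
        x = np.concatenate([np.zeros(25), np.ones(25)])
        x += np.random.default_rng(1).normal(0, 1e-3, size=50)
        assert normality_test(x) < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            normality_test([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            normality_test([3.0] * 10)


class TestCombinedIndex:
    def _table(self, n=4):
        return pd.DataFrame({"Abd_L": np.full(n, 0.90), "Abd_P": np.full(n, 0.06)})

    def test_plain_is_identity(self):
        vi = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.array_equal(combined_index(vi, self._table(), "plain"), vi)

    def test_lp_arithmetic(self):
        t = self._table(1)
        out = combined_index(np.array([0.5]), t, "LP")
        assert out[0] == pytest.approx(0.5 * (0.90 - 0.06), abs=1e-12)
        assert out[0] == pytest.approx(0.42)

    def test_abundance_closure_propagates(self):
        rng = np.random.default_rng(3)
        ab = rng.dirichlet(np.ones(3), size=8)  # leaf, panicle, soil
        t = pd.DataFrame({"Abd_L": ab[:, 0], "Abd_P": ab[:, 1]})
        vi = rng.uniform(0.1, 0.8, size=8)
        total = (combined_index(vi, t, "L") + combined_index(vi, t, "P")
                 + vi * ab[:, 2])
        assert np.allclose(total, vi, atol=1e-12)

    def test_schema_errors(self):
        with pytest.raises(KeyError):
            combined_index(np.ones(3), pd.DataFrame({"Abd_L": np.ones(3)}), "P")
        with pytest.raises(ValueError, match="mode"):
            combined_index(np.ones(3), self._table(3), "XY")


class TestCorrelation:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.2, 2.7, 3.1, 5.0])
        y = np.array([1.0, 0.4, 2.2, 3.3, 2.8])
        r0 = pearson(x, y)[0]
        assert pearson(a * x + b, y)[0] == pytest.approx(r0, abs=1e-9)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, _ = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(5), np.arange(5.0))

    def test_correlate_table_and_stars(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        t = pd.DataFrame({"yield": 2 * x + rng.normal(0, 0.1, 30)})
        out = correlate(t, {"x": x, "noise": rng.normal(size=30)})
        assert out.loc[out["predictor"] == "x", "significance"].item() == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.5) == ""


class TestFitLinear:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 10)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse < 1e-12

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=23)
        y = x + rng.normal(0, 1.0, 23)
        fit = fit_linear(x, y)
        assert fit.adjusted_r2 == pytest.approx(
            1 - (1 - fit.r2) * (23 - 1) / (23 - 2), abs=1e-12)
        # spot value: R^2 = 0.58 at n = 23 implies adjusted R^2 = 0.56
        assert 1 - (1 - 0.58) * 22 / 21 == pytest.approx(0.56, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 40)
        y = 1.3 * x - 0.4 + rng.normal(0, 0.5, 40)
        fit = fit_linear(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.rmse == pytest.approx(np.sqrt(np.mean(resid ** 2)), abs=1e-10)
        assert fit.pearson_r ** 2 == pytest.approx(fit.r2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_linear(np.ones(5), np.arange(5.0))


class TestLoocv:
    def test_noiseless_line_recovers_coefficients_in_every_fold(self):
        x = np.linspace(0, 2, 10)
        cv = loocv_fit(x, 2 * x + 1)
        assert np.allclose(cv.fold_coefficients[:, 0], 2.0, atol=1e-10)
        assert np.allclose(cv.fold_coefficients[:, 1], 1.0, atol=1e-10)
        assert cv.rmse < 1e-10
        assert cv.r2 == pytest.approx(1.0, abs=1e-12)

    def test_fold_count_equals_sample_count(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=23)
        y = x + rng.normal(0, 0.3, 23)
        cv = loocv_fit(x, y)
        assert cv.k == 23
        assert cv.fold_errors.shape == (23,)

    def test_aggregates_match_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 16)
        y = 3 * x + rng.normal(0, 0.4, 16)
        cv = loocv_fit(x, y)
        slope, intercept, r2, rmse = loocv_oracle(x, y)
        assert cv.coef[0] == pytest.approx(slope, abs=1e-12)
        assert cv.coef[1] == pytest.approx(intercept, abs=1e-12)
        assert cv.r2 == pytest.approx(r2, abs=1e-12)
        assert cv.rmse == pytest.approx(rmse, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            loocv_fit(np.arange(3.0), np.arange(3.0))


class TestRankModels:
    def _table(self, n=24, seed=10):
        rng = np.random.default_rng(seed)
        ab_l = rng.uniform(0.8, 0.99, n)
        ab_p = rng.uniform(0.0, 0.15, n)
        ndre = rng.uniform(0.3, 0.6, n)
        y = 5 * ndre * (ab_l - ab_p) + rng.normal(0, 0.2, n)
        return pd.DataFrame({"plot_id": [f"P{i}" for i in range(n)],
                             "NDRE": ndre, "Abd_L": ab_l, "Abd_P": ab_p,
                             "yield": y})

    def test_grid_size_and_sorting(self):
        out = rank_models(self._table(), ["NDRE"], ("plain", "L", "P", "LP"))
        assert len(out) == 4
        assert (out["adjusted_r2"].diff().dropna() <= 1e-12).all()

    def test_exclude_plots(self):
        out = rank_models(self._table(), ["NDRE"], ("plain",),
                          exclude_plots=("P0", "P1"))
        assert out["n"].iloc[0] == 22
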