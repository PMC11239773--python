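"""Model grid, OLS, cluster sandwich variance, correction, Wald tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crthte import (
    MODEL_GRID,
    DegenerateDesignError,
    ModelSpec,
    apply_small_sample_correction,
    build_design_matrix,
    cluster_sandwich_variance,
    fit_model,
    fit_ols,
    wald_tests,
)


def double_loop_sandwich(X, resid, cluster_ids):
    """Independent brute-force sandwich: explicit per-cluster loops."""
    p = X.shape[1]
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((p, p))
    for cid in set(cluster_ids.tolist()):
        rows = [i for i, c in enumerate(cluster_ids) if c == cid]
        s = np.zeros(p)
        for i in rows:
            for j in range(p):
                s[j] += X[i, j] * resid[i]
        meat += np.outer(s, s)
    return bread @ meat @ bread


class TestModelGrid:
    def test_sixteen_models(self):
        assert len(MODEL_GRID) == 16
        assert sum(m.level == "individual" for m in MODEL_GRID.values()) == 6
        assert sum(m.level == "cluster" for m in MODEL_GRID.values()) == 10

    def test_proportion_and_indicator_alternate(self):
        for mid in ("2c", "2e", "2g", "2i"):
            assert MODEL_GRID[mid].race_encoding == "proportion"
        for mid in ("2d", "2f", "2h", "2j"):
            assert MODEL_GRID[mid].race_encoding == "indicator"

    def test_hte_race_models(self):
        for mid in ("1e", "1f", "2g", "2h", "2i", "2j"):
            assert MODEL_GRID[mid].hte_race

    def test_race_hte_requires_race_adjustment(self):
        with pytest.raises(ValueError, match="adjust_race"):
            ModelSpec(model_id="x", level="individual", hte_race=True)

    def test_individual_models_use_raw_binary(self):
        with pytest.raises(ValueError):
            ModelSpec(
                model_id="x", level="individual", adjust_race=True,
                race_encoding="proportion",
            )


class TestDesignMatrix:
    def test_base_model_has_four_columns(self, tiny):
        X, y, ids, names = build_design_matrix(tiny["individuals"], MODEL_GRID["1a"])
        assert names == ["intercept", "intervention", "urban", "region"]
        assert X.shape == (len(tiny["individuals"]), 4)

    def test_full_cluster_model_columns(self, medium_dataset):
        summaries = medium_dataset["summaries"]
        X, y, ids, names = build_design_matrix(summaries, MODEL_GRID["2i"])
        assert names == [
            "intercept", "intervention", "urban", "region", "race",
            "trt_x_urban", "trt_x_race",
        ]
        # race column is the centered proportion for 2i
        np.testing.assert_allclose(X[:, 4], summaries["race_proportion_centered"])
        np.testing.assert_allclose(y, summaries["mean_outcome"])

    def test_interactions_are_products_of_main_effects(self, medium_dataset):
        X, _, _, names = build_design_matrix(
            medium_dataset["individuals"], MODEL_GRID["1f"]
        )
        np.testing.assert_array_equal(X[:, names.index("trt_x_urban")],
                                      X[:, 1] * X[:, 2])
        np.testing.assert_array_equal(X[:, names.index("trt_x_race")],
                                      X[:, 1] * X[:, 4])

    def test_constant_race_column_flagged(self, tiny):
        individuals = tiny["individuals"].copy()
        individuals["race"] = 0
        with pytest.raises(DegenerateDesignError, match="race"):
            build_design_matrix(individuals, MODEL_GRID["1f"])

    def test_fit_model_records_degeneracy_instead_of_raising(self, tiny):
        individuals = tiny["individuals"].copy()
        individuals["race"] = 0
        result = fit_model(individuals, MODEL_GRID["1f"])
        assert result.degenerate and result.table is None


class TestOls:
    def test_exact_linear_response_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.random((30, 2)).round(2)])
        beta_true = np.array([0.5, -1.0, 2.0])
        beta, resid = fit_ols(X, X @ beta_true)
        np.testing.assert_allclose(beta, beta_true, atol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_saturated_two_by_two_equals_cell_means(self):
        # y means per (a, z) cell; coefficients are the standard contrasts.
        a = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        z = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        y = np.array([0.2, 0.4, 0.5, 0.9, 0.3, 0.5, 0.6, 1.0])
        X = np.column_stack([np.ones(8), a, z, a * z])
        beta, _ = fit_ols(X, y)
        m00 = y[(a == 0) & (z == 0)].mean()
        m01 = y[(a == 0) & (z == 1)].mean()
        m10 = y[(a == 1) & (z == 0)].mean()
        m11 = y[(a == 1) & (z == 1)].mean()
        np.testing.assert_allclose(
            beta, [m00, m10 - m00, m01 - m00, (m11 - m10) - (m01 - m00)],
            atol=1e-12,
        )

    def test_matches_normal_equations_oracle(self, medium_dataset):
        X, y, _, _ = build_design_matrix(
            medium_dataset["individuals"], MODEL_GRID["1f"]
        )
        beta, _ = fit_ols(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_rank_deficiency_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(DegenerateDesignError, match="rank"):
            fit_ols(X, np.ones(10))


class TestSandwich:
    def test_zero_residuals_give_zero_matrix(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(12), rng.random(12)])
        ids = np.repeat([1, 2, 3], 4)
        cov = cluster_sandwich_variance(X, np.zeros(12), ids)
        np.testing.assert_allclose(cov, 0.0, atol=1e-15)

    def test_matches_double_loop_oracle_k6(self):
        rng = np.random.default_rng(2)
        n, K = 36, 6
        X = np.column_stack([np.ones(n), rng.random((n, 3))])
        resid = rng.normal(size=n)
        ids = np.repeat(np.arange(K), n // K)
        cov = cluster_sandwich_variance(X, resid, ids)
        np.testing.assert_allclose(
            cov, double_loop_sandwich(X, resid, ids), rtol=1e-12, atol=1e-15
        )

    def test_unsorted_cluster_ids_handled(self):
        rng = np.random.default_rng(3)
        n = 30
        X = np.column_stack([np.ones(n), rng.random(n)])
        resid = rng.normal(size=n)
        ids = rng.integers(0, 5, size=n)
        np.testing.assert_allclose(
            cluster_sandwich_variance(X, resid, ids),
            double_loop_sandwich(X, resid, ids),
            rtol=1e-12,
        )

    def test_one_observation_per_cluster_is_hc0(self):
        rng = np.random.default_rng(4)
        n = 20
        X = np.column_stack([np.ones(n), rng.random(n)])
        resid = rng.normal(size=n)
        ids = np.arange(n)
        bread = np.linalg.inv(X.T @ X)
        hc0 = bread @ (X.T @ np.diag(resid**2) @ X) @ bread
        np.testing.assert_allclose(
            cluster_sandwich_variance(X, resid, ids), hc0, rtol=1e-12
        )

    def test_symmetric_positive_semidefinite(self, medium_dataset):
        for mid in ("1a", "1f", "2a", "2i", "2j"):
            spec = MODEL_GRID[mid]
            data = (
                medium_dataset["individuals"]
                if spec.level == "individual"
                else medium_dataset["summaries"]
            )
            X, y, ids, _ = build_design_matrix(data, spec)
            _, resid = fit_ols(X, y)
            cov = cluster_sandwich_variance(X, resid, ids)
            np.testing.assert_allclose(cov, cov.T, rtol=1e-10)
            assert np.linalg.eigvalsh(cov).min() > -1e-12

    def test_statsmodels_cluster_covariance_agrees(self, medium_dataset):
        sm = pytest.importorskip("statsmodels.api")
        X, y, ids, _ = build_design_matrix(
            medium_dataset["individuals"], MODEL_GRID["1e"]
        )
        _, resid = fit_ols(X, y)
        ours = cluster_sandwich_variance(X, resid, ids)
        fit = sm.OLS(y, X).fit(
            cov_type="cluster",
            cov_kwds={"groups": ids, "use_correction": False, "df_correction": False},
        )
        np.testing.assert_allclose(ours, fit.cov_params(), rtol=1e-8)

    def test_gee_independence_equals_ols_on_cluster_data(self, medium_dataset):
        # The estimating equations with identity link and independence
        # working correlation reduce to least squares on cluster-level
        # data; point estimates must agree to machine precision.
        sm = pytest.importorskip("statsmodels.api")
        X, y, ids, _ = build_design_matrix(
            medium_dataset["summaries"], MODEL_GRID["2i"]
        )
        beta, _ = fit_ols(X, y)
        gee = sm.GEE(
            y, X, groups=ids,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        np.testing.assert_allclose(beta, gee.params, rtol=1e-10, atol=1e-12)


class TestCorrectionAndWald:
    @pytest.mark.parametrize("K,mult", [(40, 40 / 38), (30, 30 / 28), (1000, 1000 / 998)])
    def test_small_sample_multiplier(self, K, mult):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(
            apply_small_sample_correction(cov, K), cov * mult, rtol=1e-15
        )

    @pytest.mark.parametrize("K", [1, 2])
    def test_correction_needs_more_than_two_clusters(self, K):
        with pytest.raises(ValueError):
            apply_small_sample_correction(np.eye(2), K)

    def test_null_estimate_gives_p_one(self):
        table = wald_tests(np.array([0.0]), np.array([[1.0]]), ["b"])
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert not table["reject"].iloc[0]

    def test_critical_value_boundary(self):
        table = wald_tests(np.array([1.96]), np.array([[1.0]]), ["b"])
        assert table["p"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_p_values_match_erfc_oracle(self, medium_dataset):
        result = fit_model(medium_dataset["individuals"], MODEL_GRID["1f"])
        for _, row in result.table.iterrows():
            oracle = math.erfc(abs(row["statistic"]) / math.sqrt(2))
            assert row["p"] == pytest.approx(oracle, rel=1e-10)

    def test_zero_se_recorded_as_degenerate(self):
        table = wald_tests(np.array([1.0]), np.array([[0.0]]), ["b"])
        assert table["degenerate"].iloc[0]
        assert np.isnan(table["p"].iloc[0])
        assert not table["reject"].iloc[0]

    def test_t_reference_widens_p_values(self, medium_dataset):
        z = fit_model(medium_dataset["summaries"], MODEL_GRID["2g"])
        t = fit_model(
            medium_dataset["summaries"], MODEL_GRID["2g"], reference="t"
        )
        assert (t.table["p"] >= z.table["p"] - 1e-12).all()

    @given(st.integers(3, 200))
    def test_correction_shrinks_to_one(self, K):
        corrected = apply_small_sample_correction(np.eye(1), K)
        assert corrected[0, 0] == pytest.approx(K / (K - 2))
        assert corrected[0, 0] > 1.0
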