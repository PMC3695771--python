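"""Exact semi-parallel linear regression: projections, estimates, p-values."""

import numpy as np
import pytest

from semigwas import (
    assoc_linear,
    assoc_linear_nocov,
    build_linear_context,
    log10_pvalue_twosided,
    project_block,
    simulate_quantitative_study,
)
from semigwas.oracle import ols_per_snp


class TestNullContext:
    def test_intercept_only_residualizes_to_centered_y(self, rng):
        y = rng.standard_normal(20)
        ctx = build_linear_context(y, None)
        np.testing.assert_allclose(ctx.y_star, y - y.mean(), atol=1e-14)

    def test_y_in_covariate_span_gives_zero_residual(self, rng):
        X = np.column_stack([np.ones(15), rng.standard_normal((15, 2))])
        y = X @ np.array([1.0, -2.0, 0.5])
        ctx = build_linear_context(y, X)
        assert np.abs(ctx.y_star).max() <= 1e-10 * np.linalg.norm(y)

    def test_residual_orthogonal_to_covariates(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 3))])
        y = rng.standard_normal(20)
        ctx = build_linear_context(y, X)
        assert np.abs(X.T @ ctx.y_star).max() <= 1e-10 * np.linalg.norm(y)

    def test_intercept_prepended_when_absent(self, rng):
        ctx = build_linear_context(rng.standard_normal(10), rng.standard_normal((10, 2)))
        assert ctx.X.shape[1] == 3 and np.all(ctx.X[:, 0] == 1)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="column"):
            build_linear_context(rng.standard_normal(20), X)

    def test_insufficient_sample_errors(self, rng):
        with pytest.raises(ValueError, match="n > k"):
            build_linear_context(rng.standard_normal(4), rng.standard_normal((4, 3)))


class TestProjection:
    def test_constant_snp_column_vanishes(self, rng):
        ctx = build_linear_context(rng.standard_normal(12), rng.standard_normal((12, 2)))
        s_star = project_block(ctx, np.full((12, 1), 1.7))
        assert np.abs(s_star).max() < 1e-12

    def test_intercept_only_projection_centers_columns(self, rng):
        S = rng.uniform(0, 2, size=(30, 5))
        ctx = build_linear_context(rng.standard_normal(30), None)
        np.testing.assert_allclose(project_block(ctx, S), S - S.mean(axis=0), atol=1e-13)

    def test_orthogonality_and_idempotence(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 4))])
        ctx = build_linear_context(rng.standard_normal(50), X)
        S = rng.uniform(0, 2, size=(50, 8))
        s_star = project_block(ctx, S)
        assert np.abs(X.T @ s_star).max() <= 1e-8 * np.linalg.norm(S)
        np.testing.assert_allclose(project_block(ctx, s_star), s_star, atol=1e-12)

    def test_row_mismatch_errors(self, rng):
        ctx = build_linear_context(rng.standard_normal(10), None)
        with pytest.raises(ValueError, match="rows"):
            project_block(ctx, np.ones((11, 2)))


class TestAssocLinear:
    @pytest.mark.parametrize("k", [0, 2, 10, 30])
    def test_matches_per_snp_ols(self, k):
        """The core contract: block algebra equals per-SNP textbook OLS."""
        y, X, block = simulate_quantitative_study(200, 30, k, seed=11 + k)
        ctx = build_linear_context(y, X)
        res = assoc_linear(ctx, project_block(ctx, block), block.snp_ids)
        for j in range(block.n_snps):
            fit = ols_per_snp(y, X, block.doses[:, j])
            assert res.beta[j] == pytest.approx(fit.snp_beta, rel=1e-8)
            assert res.se[j] == pytest.approx(fit.snp_se, rel=1e-8)
            stat = fit.snp_beta / fit.snp_se
            assert res.log10_p[j] == pytest.approx(
                float(log10_pvalue_twosided(stat)), rel=1e-8
            )

    def test_toy_slope_by_hand(self):
        # y=(1,2,3,4) on s=(0,1,1,2): slope = sum(sc*yc)/sum(sc^2) = 3/2
        y = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([0.0, 1.0, 1.0, 2.0])
        res = assoc_linear_nocov(y, s[:, None])
        assert res.beta[0] == pytest.approx(1.5, rel=1e-12)

    def test_perfect_fit(self, rng):
        ctx = build_linear_context(rng.standard_normal(10), None)
        s_star = ctx.y_star / 2.0
        res = assoc_linear(ctx, s_star[:, None], ["s"])
        assert res.beta[0] == pytest.approx(2.0, rel=1e-12)
        assert res.se[0] == 0.0

    def test_zero_column_is_monomorphic_without_killing_block(self, rng):
        ctx = build_linear_context(rng.standard_normal(40), None)
        S = rng.uniform(0, 2, size=(40, 3))
        S[:, 1] = 1.0  # constant -> zero residual
        res = assoc_linear(ctx, project_block(ctx, S), ["a", "b", "c"])
        assert list(res.status) == ["ok", "monomorphic", "ok"]
        assert np.isnan(res.beta[1]) and np.isfinite(res.beta[[0, 2]]).all()

    def test_reparameterization_invariance(self, rng):
        """Replacing X by X @ T (same column space) leaves results unchanged."""
        y, X, block = simulate_quantitative_study(150, 10, 3, seed=5)
        T = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        res1 = _scan(y, X, block)
        res2 = _scan(y, X @ T, block)
        np.testing.assert_allclose(res1.beta, res2.beta, rtol=1e-8)
        np.testing.assert_allclose(res1.se, res2.se, rtol=1e-8)

    def test_block_partition_independence(self):
        y, X, block = simulate_quantitative_study(100, 23, 2, seed=7)
        ctx = build_linear_context(y, X)
        whole = assoc_linear(ctx, project_block(ctx, block), block.snp_ids)
        pieces = [
            assoc_linear(
                ctx,
                project_block(ctx, block.doses[:, lo : lo + 7]),
                block.snp_ids[lo : lo + 7],
            )
            for lo in range(0, 23, 7)
        ]
        import pandas as pd

        np.testing.assert_allclose(
            pd.concat(pieces, ignore_index=True)["beta"], whole["beta"], rtol=1e-12
        )

    def test_fused_scan_path_equals_projected_route(self):
        """scan_block (no S* materialized) matches project + associate."""
        from semigwas.linear import scan_block

        y, X, block = simulate_quantitative_study(400, 50, 5, seed=8)
        ctx = build_linear_context(y, X)
        fused = scan_block(ctx, block)
        routed = assoc_linear(ctx, project_block(ctx, block), block.snp_ids)
        np.testing.assert_allclose(fused["beta"], routed["beta"], rtol=1e-8)
        np.testing.assert_allclose(fused["se"], routed["se"], rtol=1e-8)
        np.testing.assert_allclose(fused["log10_p"], routed["log10_p"], rtol=1e-8)


def _scan(y, X, block):
    ctx = build_linear_context(y, X)
    return assoc_linear(ctx, project_block(ctx, block), block.snp_ids)


class TestNoCovariatePath:
    def test_identical_to_intercept_only_engine(self):
        y, _, block = simulate_quantitative_study(120, 15, 0, seed=9)
        res_fast = assoc_linear_nocov(y, block, block.snp_ids)
        res_full = _scan(y, None, block)
        np.testing.assert_allclose(res_fast.beta, res_full.beta, rtol=1e-10)
        np.testing.assert_allclose(res_fast.se, res_full.se, rtol=1e-10)
        np.testing.assert_allclose(res_fast.log10_p, res_full.log10_p, rtol=1e-10)

    def test_constant_phenotype_gives_zero_betas(self, rng):
        res = assoc_linear_nocov(np.full(30, 2.5), rng.uniform(0, 2, (30, 4)))
        np.testing.assert_allclose(res.beta, 0.0, atol=1e-12)

    def test_constant_snp_is_monomorphic(self, rng):
        res = assoc_linear_nocov(rng.standard_normal(30), np.ones((30, 1)))
        assert res.status[0] == "monomorphic"


class TestLogPvalue:
    def test_zero_stat_gives_p_one(self):
        assert log10_pvalue_twosided(0.0) == 0.0

    def test_five_percent_point(self):
        assert log10_pvalue_twosided(1.959964) == pytest.approx(-1.30103, abs=1e-4)

    def test_deep_tail_matches_mills_ratio_asymptotics(self):
        """Finite log p far past linear-scale underflow, agreeing with the
        independent asymptotic expansion of the normal tail."""
        for t in (10.0, 20.0, 40.0, 100.0, 200.0):
            got = log10_pvalue_twosided(t)
            assert np.isfinite(got)
            # log Phi(-t) ~ -t^2/2 - log t - log sqrt(2 pi) + log(1 - t^-2 + 3 t^-4 ...)
            series = 1 - t**-2 + 3 * t**-4 - 15 * t**-6 + 105 * t**-8
            expected = (
                np.log10(2.0)
                + (-0.5 * t**2 - np.log(t) - 0.5 * np.log(2 * np.pi) + np.log(series))
                / np.log(10.0)
            )
            assert got == pytest.approx(expected, rel=1e-6)
        assert log10_pvalue_twosided(40.0) == pytest.approx(-349.1, abs=0.5)

    def test_strictly_decreasing_in_stat_magnitude(self):
        stats = np.linspace(0, 200, 2001)
        vals = log10_pvalue_twosided(stats)
        assert np.all(np.diff(vals[1:]) < 0) and vals[1] < vals[0]

    def test_student_reference_and_df_validation(self):
        # t reference is heavier-tailed than normal at small df
        assert log10_pvalue_twosided(3.0, "student", df=5) > float(
            log10_pvalue_twosided(3.0)
        )
        with pytest.raises(ValueError):
            log10_pvalue_twosided(3.0, "student", df=0)
        with pytest.raises(ValueError):
            log10_pvalue_twosided(3.0, "cauchy")
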