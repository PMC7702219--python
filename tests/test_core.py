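"""Unit tests for the SVD-based fractional ridge solver."""

import numpy as np
import pytest

from fractional_ridge.core import (
    AlphaGrid,
    DegenerateDesignError,
    DimensionError,
    InternalConsistencyError,
    InvalidInputError,
    ParameterError,
    RotatedTarget,
    ZeroNormTargetError,
    build_alpha_grid,
    decompose_design,
    frr,
    gamma_curve,
    interpolate_alphas,
    ridge_direct,
    rotate_target,
    shrinkage_factors,
    solve_target,
    unrotate,
)


class TestDecomposeDesign:
    def test_identity_design(self):
        dec = decompose_design(np.eye(3))
        np.testing.assert_allclose(dec.singular_values, [1, 1, 1])
        np.testing.assert_allclose(np.abs(dec.right_rotation), np.eye(3), atol=1e-12)
        assert dec.rank == 3

    def test_diagonal_design(self):
        X = np.array([[2.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        dec = decompose_design(X)
        np.testing.assert_allclose(dec.singular_values, [2, 1])

    def test_duplicate_columns_truncate_rank(self, rng):
        X = rng.standard_normal((4, 3))
        X[:, 2] = X[:, 0]
        dec = decompose_design(X)
        assert dec.rank == 2
        recon = dec.target_projector @ np.diag(dec.singular_values) @ dec.right_rotation.T
        # X itself is rank 2, so the retained space reconstructs it fully
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) <= 1e-8

    def test_reconstruction_and_orthonormality(self, rng):
        X = rng.standard_normal((8, 5))
        dec = decompose_design(X)
        V = dec.right_rotation
        np.testing.assert_allclose(V.T @ V, np.eye(dec.rank), atol=1e-10)
        recon = dec.target_projector @ np.diag(dec.singular_values) @ V.T
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) <= 1e-10

    def test_gram_route_matches_svd(self, rng):
        X = rng.standard_normal((40, 7))
        dg = decompose_design(X, method="gram")
        ds = decompose_design(X, method="svd")
        np.testing.assert_allclose(dg.singular_values, ds.singular_values, rtol=1e-8)
        # compare rotations up to per-column sign
        for k in range(dg.rank):
            a, b = dg.right_rotation[:, k], ds.right_rotation[:, k]
            assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-8

    def test_nonfinite_raises(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(InvalidInputError):
            decompose_design(X)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateDesignError):
            decompose_design(np.zeros((4, 3)))


class TestRotateTarget:
    def test_identity_design(self):
        dec = decompose_design(np.eye(3))
        t = rotate_target(dec, np.array([3.0, 4.0, 0.0]))
        np.testing.assert_allclose(np.abs(t.y_rot), [3, 4, 0])
        np.testing.assert_allclose(np.abs(t.beta_ols_rot), [3, 4, 0])
        assert t.ols_norm == pytest.approx(5.0)

    def test_componentwise_division(self):
        # lambda=(2,1), y_rot=(4,3) -> beta_ols_rot=(2,3)
        dec = decompose_design(np.diag([2.0, 1.0]))
        t = rotate_target(dec, np.array([4.0, 3.0]))
        np.testing.assert_allclose(t.beta_ols_rot, [2.0, 3.0])

    def test_zero_target(self):
        dec = decompose_design(np.eye(3))
        t = rotate_target(dec, np.zeros(3))
        assert t.ols_norm == 0.0
        np.testing.assert_array_equal(t.beta_ols_rot, 0.0)

    def test_length_mismatch(self):
        dec = decompose_design(np.eye(3))
        with pytest.raises(DimensionError):
            rotate_target(dec, np.zeros(4))


class TestAlphaGrid:
    def test_unit_spectrum_31_points(self):
        dec = decompose_design(np.eye(2))
        grid = build_alpha_grid(dec)
        assert grid.alphas.size == 31
        assert grid.alphas[0] == pytest.approx(1e-3)
        assert grid.alphas[-1] == pytest.approx(1e3)

    def test_span_covers_spectrum(self):
        dec = decompose_design(np.diag([10.0, 0.1]))
        grid = build_alpha_grid(dec)
        assert grid.alphas[0] <= 1e-3 * 0.1**2 * (1 + 1e-9)
        assert grid.alphas[-1] >= 1e3 * 10.0**2 * (1 - 1e-9)

    def test_constant_log_spacing(self, rng):
        X = rng.standard_normal((20, 6))
        grid = build_alpha_grid(decompose_design(X))
        steps = np.diff(np.log10(grid.alphas))
        np.testing.assert_allclose(steps, 0.2, atol=1e-12)

    def test_nonpositive_spacing_raises(self):
        dec = decompose_design(np.eye(2))
        with pytest.raises(ParameterError):
            build_alpha_grid(dec, log_spacing=0.0)


class TestShrinkageFactors:
    def test_known_values(self):
        dec = decompose_design(np.diag([2.0, 1.0]))
        grid = AlphaGrid(np.array([1.0]), 0.2, 0.0, 0.0)
        sf = shrinkage_factors(dec, grid).factors
        np.testing.assert_allclose(sf[:, 0], [0.8, 0.5])

    def test_rows_decrease_with_alpha(self, rng):
        X = rng.standard_normal((15, 4))
        dec = decompose_design(X)
        sf = shrinkage_factors(dec, build_alpha_grid(dec)).factors
        assert np.all(np.diff(sf, axis=1) < 0)
        assert np.all((sf > 0) & (sf < 1))

    def test_max_alpha_bound(self, rng):
        X = rng.standard_normal((15, 4))
        dec = decompose_design(X)
        sf = shrinkage_factors(dec, build_alpha_grid(dec)).factors
        # alpha >= 1e3*lambda_1^2 shrinks every component below ~1e-3
        assert np.all(sf[:, -1] <= 1e-3)


class TestGammaCurve:
    def test_flat_spectrum_half(self):
        dec = decompose_design(np.eye(3) * 2.0)
        tgt = rotate_target(dec, np.array([1.0, -2.0, 0.5]))
        grid = AlphaGrid(np.array([4.0]), 0.2, 0.0, 0.0)  # alpha = lambda^2
        g = gamma_curve(tgt, shrinkage_factors(dec, grid))
        assert g[0] == pytest.approx(0.5)

    def test_single_component(self):
        dec = decompose_design(np.eye(1))
        tgt = rotate_target(dec, np.array([2.0]))
        grid = AlphaGrid(np.array([3.0]), 0.2, 0.0, 0.0)
        g = gamma_curve(tgt, shrinkage_factors(dec, grid))
        assert g[0] == pytest.approx(0.25)

    def test_strictly_decreasing_and_bounded(self, rng):
        X = rng.standard_normal((30, 6))
        dec = decompose_design(X)
        grid = build_alpha_grid(dec)
        tgt = rotate_target(dec, rng.standard_normal(30))
        g = gamma_curve(tgt, shrinkage_factors(dec, grid))
        assert np.all(np.diff(g) < 0)
        assert np.all((g > 0) & (g < 1))
        # at the grid minimum every component retains >= 1/(1+1e-3)
        assert g[0] >= 1.0 / (1.0 + 1e-3)

    def test_zero_norm_raises(self):
        dec = decompose_design(np.eye(2))
        tgt = rotate_target(dec, np.zeros(2))
        grid = build_alpha_grid(dec)
        with pytest.raises(ZeroNormTargetError):
            gamma_curve(tgt, shrinkage_factors(dec, grid))


class TestInterpolateAlphas:
    def _flat_setup(self):
        dec = decompose_design(np.eye(4))
        grid = build_alpha_grid(dec)
        tgt = rotate_target(dec, np.array([1.0, 2.0, -1.0, 0.5]))
        g = gamma_curve(tgt, shrinkage_factors(dec, grid))
        return g, grid

    def test_endpoints(self):
        g, grid = self._flat_setup()
        a = interpolate_alphas(g, grid, [0.0, 1.0])
        assert a[1] == 0.0
        assert np.isinf(a[0])

    def test_flat_spectrum_closed_form(self):
        g, grid = self._flat_setup()
        a = interpolate_alphas(g, grid, [0.5])
        # closed form: alpha = lambda^2 (1/gamma - 1) = 1 at gamma = 0.5
        assert a[0] == pytest.approx(1.0, rel=0.02)

    def test_non_monotone_raises(self):
        _, grid = self._flat_setup()
        bad = np.linspace(1, 0, grid.alphas.size)
        bad[3] = bad[2] + 0.1
        with pytest.raises(InternalConsistencyError):
            interpolate_alphas(bad, grid, [0.5])


class TestSolveTarget:
    def _dec_target(self):
        dec = decompose_design(np.diag([2.0, 1.0]))
        tgt = RotatedTarget(np.array([4.0, 3.0]), np.array([2.0, 3.0]), float(np.sqrt(13)))
        return dec, tgt

    def test_zero_penalty_is_ols_exact(self):
        dec, tgt = self._dec_target()
        out = solve_target(tgt, dec, np.array([0.0]))
        np.testing.assert_array_equal(out[:, 0], tgt.beta_ols_rot)

    def test_componentwise_shrinkage(self):
        dec, tgt = self._dec_target()
        out = solve_target(tgt, dec, np.array([1.0]))
        np.testing.assert_allclose(out[:, 0], [1.6, 1.5])

    def test_inf_sentinel_zeros(self):
        dec, tgt = self._dec_target()
        out = solve_target(tgt, dec, np.array([np.inf]))
        np.testing.assert_array_equal(out, 0.0)


class TestUnrotate:
    def test_identity(self):
        dec = decompose_design(np.eye(3))
        b = np.arange(6.0).reshape(3, 2)
        np.testing.assert_allclose(np.abs(unrotate(dec, b)), b, atol=1e-12)

    def test_norm_preserved(self, rng):
        X = rng.standard_normal((20, 6))
        dec = decompose_design(X)
        b = rng.standard_normal((dec.rank, 3))
        out = unrotate(dec, b)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=0), np.linalg.norm(b, axis=0), atol=1e-10
        )

    def test_truncated_output_in_retained_span(self, rng):
        X = rng.standard_normal((6, 4))
        X[:, 3] = X[:, 0]  # rank 3
        dec = decompose_design(X)
        assert dec.rank == 3
        b = rng.standard_normal((dec.rank, 2))
        out = unrotate(dec, b)
        # project onto discarded right-singular directions: should vanish
        full_v = np.linalg.svd(X)[2].T
        discarded = full_v[:, dec.rank :]
        assert np.linalg.norm(discarded.T @ out) <= 1e-10

    def test_dimension_mismatch(self):
        dec = decompose_design(np.eye(3))
        with pytest.raises(DimensionError):
            unrotate(dec, np.zeros((2, 1)))


class TestFRR:
    def test_gamma_one_is_least_squares(self, tall_problem):
        X, Y = tall_problem
        sol = frr(X, Y, [1.0])
        beta_ls, *_ = np.linalg.lstsq(X, Y, rcond=None)
        np.testing.assert_allclose(sol.coefs[:, 0, :], beta_ls, atol=1e-10)
        np.testing.assert_allclose(sol.achieved_fractions[0], 1.0)
        np.testing.assert_array_equal(sol.alphas[0], 0.0)

    def test_fraction_accuracy(self, tall_problem):
        X, Y = tall_problem
        fracs = np.round(np.arange(0.05, 0.951, 0.05), 10)
        sol = frr(X, Y, fracs)
        dev = np.abs(sol.achieved_fractions - fracs[:, None])
        assert dev.max() <= 0.01

    def test_matches_direct_ridge(self, tall_problem):
        X, Y = tall_problem
        fracs = [0.2, 0.5, 0.8]
        sol = frr(X, Y, fracs)
        for k in range(Y.shape[1]):
            for j in range(len(fracs)):
                bd = ridge_direct(X, Y[:, k], sol.alphas[j, k])
                rel = np.linalg.norm(sol.coefs[:, j, k] - bd) / np.linalg.norm(bd)
                assert rel <= 1e-6

    def test_coefficient_norms_increase_with_fraction(self, tall_problem):
        X, Y = tall_problem
        fracs = np.round(np.arange(0.1, 1.01, 0.1), 10)
        sol = frr(X, Y, fracs)
        norms = np.linalg.norm(sol.coefs, axis=0)
        assert np.all(np.diff(norms, axis=0) > 0)

    def test_caller_fraction_order_preserved(self, tall_problem):
        X, Y = tall_problem
        shuffled = [0.7, 0.2, 1.0, 0.2]
        sol = frr(X, Y, shuffled)
        ref = frr(X, Y, [0.2, 0.7, 1.0])
        np.testing.assert_array_equal(sol.fractions, shuffled)
        np.testing.assert_array_equal(sol.coefs[:, 0, :], ref.coefs[:, 1, :])
        np.testing.assert_array_equal(sol.coefs[:, 1, :], ref.coefs[:, 0, :])
        np.testing.assert_array_equal(sol.coefs[:, 3, :], ref.coefs[:, 0, :])

    def test_zero_fraction_exact_zeros(self, tall_problem):
        X, Y = tall_problem
        sol = frr(X, Y, [0.0])
        np.testing.assert_array_equal(sol.coefs, 0.0)
        assert np.all(np.isinf(sol.alphas))

    def test_degenerate_target_nan_bookkeeping(self, rng):
        X = rng.standard_normal((10, 3))
        Y = np.zeros((10, 2))
        Y[:, 1] = rng.standard_normal(10)
        sol = frr(X, Y, [0.5])
        np.testing.assert_array_equal(sol.coefs[:, 0, 0], 0.0)
        assert np.isnan(sol.alphas[0, 0]) and np.isnan(sol.achieved_fractions[0, 0])
        assert np.isfinite(sol.alphas[0, 1])

    def test_empty_targets(self, rng):
        X = rng.standard_normal((10, 3))
        sol = frr(X, np.zeros((10, 0)), [0.5])
        assert sol.coefs.shape == (3, 1, 0)

    def test_single_vector_target(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        sol = frr(X, y, [1.0])
        assert sol.coefs.shape == (3, 1, 1)

    def test_row_mismatch_raises(self, rng):
        with pytest.raises(DimensionError):
            frr(rng.standard_normal((10, 3)), rng.standard_normal(9), [0.5])

    def test_bad_fractions_raise(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ParameterError):
            frr(X, rng.standard_normal(10), [1.5])

    def test_shrinkage_ordering_by_singular_value(self, rng):
        """Components with larger singular values are shrunk less."""
        X = rng.standard_normal((30, 5))
        dec = decompose_design(X)
        tgt = rotate_target(dec, rng.standard_normal(30))
        for alpha in [0.1, 1.0, 10.0]:
            out = solve_target(tgt, dec, np.array([alpha]))[:, 0]
            ratios = out / tgt.beta_ols_rot
            # singular values sorted descending -> ratios sorted descending
            assert np.all(np.diff(ratios) <= 1e-12)


class TestRidgeDirect:
    def test_identity_design(self):
        beta = ridge_direct(np.eye(2), np.array([1.0, 1.0]), 1.0)
        np.testing.assert_allclose(beta, [0.5, 0.5])

    def test_alpha_zero_is_ols(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        beta = ridge_direct(X, y, 0.0)
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, beta_ne, atol=1e-10)

    def test_agrees_with_svd_route(self, rng):
        X = rng.standard_normal((6, 3))
        y = rng.standard_normal(6)
        alpha = 2.0
        U, lam, Vt = np.linalg.svd(X, full_matrices=False)
        beta_svd = Vt.T @ (lam / (lam**2 + alpha) * (U.T @ y))
        np.testing.assert_allclose(ridge_direct(X, y, alpha), beta_svd, atol=1e-10)

    def test_rank_deficient_alpha_zero_pseudoinverse(self, rng):
        X = rng.standard_normal((6, 4))
        X[:, 3] = X[:, 0]
        y = rng.standard_normal(6)
        beta = ridge_direct(X, y, 0.0)
        np.testing.assert_allclose(beta, np.linalg.pinv(X) @ y, atol=1e-10)

    def test_negative_alpha_raises(self, rng):
        with pytest.raises(ParameterError):
            ridge_direct(np.eye(2), np.ones(2), -1.0)
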