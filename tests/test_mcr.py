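import itertools

import numpy as np
import pytest

from ramanmix.mcr import (
    MCRConfig,
    apply_closure,
    apply_equality,
    compute_metrics,
    fit_mcr,
    fit_with_basis,
    nnls,
    simplisma_init,
)

from conftest import matched_correlations


def brute_force_nnls(a, b):
    """Exhaustive active-set oracle: try every pattern of clamped-to-zero
    coefficients, solve the free ones by least squares, keep the feasible
    candidate with minimal RSS."""
    n = a.shape[1]
    best_x, best_rss = np.zeros(n), float(np.sum(b**2))
    for free in itertools.chain.from_iterable(
        itertools.combinations(range(n), k) for k in range(1, n + 1)
    ):
        free = list(free)
        sol, *_ = np.linalg.lstsq(a[:, free], b, rcond=None)
        if np.any(sol < 0):
            continue
        x = np.zeros(n)
        x[free] = sol
        rss = float(np.sum((a @ x - b) ** 2))
        if rss < best_rss - 1e-12:
            best_x, best_rss = x, rss
    return best_x


class TestNnls:
    def test_matches_ols_when_unconstrained_solution_positive(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 3)) + 0.1
        x_true = np.array([1.0, 2.0, 0.5])
        b = a @ x_true
        np.testing.assert_allclose(nnls(a, b), x_true, atol=1e-10)

    def test_orthogonal_rhs_gives_zero(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        b = np.array([0.0, 0.0, 5.0])
        np.testing.assert_allclose(nnls(a, b), [0.0, 0.0], atol=1e-12)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            nnls(np.ones((4, 2)), np.ones(3))

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.standard_normal((4, 3))
            b = rng.standard_normal(4)
            np.testing.assert_allclose(
                nnls(a, b), brute_force_nnls(a, b), atol=1e-8
            )


class TestSimplisma:
    def test_pure_rows_selected(self):
        # rows 0 and 3 are exact pure components with disjoint peaks
        x = np.linspace(0.0, 1.0, 80)
        s1 = np.exp(-(((x - 0.25) / 0.04) ** 2))
        s2 = np.exp(-(((x - 0.75) / 0.04) ** 2))
        d = np.vstack([s1, 0.6 * s1 + 0.4 * s2, 0.5 * s1 + 0.5 * s2, s2])
        _, idx = simplisma_init(d, 2)
        assert set(idx) == {0, 3}

    def test_single_component_base_case(self):
        rng = np.random.default_rng(1)
        d = rng.random((6, 40))
        init, idx = simplisma_init(d, 1)
        mu = d.mean(axis=1)
        sigma = d.std(axis=1)
        alpha = 0.10 * mu.max()
        assert idx[0] == np.argmax(sigma / (mu + alpha))
        assert init.shape == (1, 40)

    def test_large_offset_limit_approaches_sigma_ordering(self):
        rng = np.random.default_rng(2)
        d = rng.random((8, 60)) + 0.5
        d /= d.mean(axis=1, keepdims=True)  # equal means isolate the limit
        _, idx = simplisma_init(d, 1, allowed_noise_pct=99.0)
        # with a large offset the denominator is ~constant: ordering by sigma
        assert idx[0] == np.argmax(d.std(axis=1))

    def test_too_many_components_errors(self):
        d = np.vstack([np.ones(10), np.ones(10), 2 * np.ones(10)])
        with pytest.raises(ValueError):
            simplisma_init(d, 3)

    def test_non_negative_estimates(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal((10, 30))
        init, _ = simplisma_init(d, 3)
        assert np.all(init >= 0)


class TestClosure:
    def test_unit_row_unchanged(self):
        s = np.ones((1, 4)) / 4.0
        out, factors = apply_closure(s)
        np.testing.assert_allclose(out, s)
        assert factors[0] == pytest.approx(1.0)

    def test_scale_absorbed(self):
        s = np.full((1, 5), 1.0)  # area 5
        c = np.array([[2.0]])
        out, factors = apply_closure(s)
        assert factors[0] == pytest.approx(5.0)
        np.testing.assert_allclose((c * factors) @ out, c @ s)

    def test_all_free_rows_unit_sum(self):
        rng = np.random.default_rng(4)
        s = rng.random((5, 30))
        out, _ = apply_closure(s)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_area_row_errors(self):
        with pytest.raises(ValueError, match="zero spectral area"):
            apply_closure(np.vstack([np.ones(4), np.zeros(4)]))

    def test_fixed_rows_untouched(self):
        s = np.vstack([np.full(4, 2.0), np.full(4, 3.0)])
        out, factors = apply_closure(s, free_mask=np.array([False, True]))
        np.testing.assert_array_equal(out[0], s[0])
        assert out[1].sum() == pytest.approx(1.0)


class TestEquality:
    def test_all_sentinel_identity(self):
        s = np.random.default_rng(0).random((3, 6))
        fixed = np.full((3, 6), np.nan)
        np.testing.assert_array_equal(apply_equality(s, fixed), s)

    def test_fixed_rows_bit_exact(self):
        rng = np.random.default_rng(1)
        s = rng.random((8, 20))
        basis = rng.random((4, 20))
        fixed = np.full((8, 20), np.nan)
        fixed[:4] = basis
        out = apply_equality(s, fixed)
        assert np.array_equal(out[:4], basis)
        np.testing.assert_array_equal(out[4:], s[4:])

    def test_negative_fixed_row_rejected_with_nonneg(self):
        fixed = np.array([[1.0, -0.5]])
        with pytest.raises(ValueError):
            apply_equality(np.ones((1, 2)), fixed, nonneg=True)


class TestMetrics:
    def test_zero_residual(self):
        m = compute_metrics(np.ones((2, 3)), np.zeros((2, 3)))
        assert m.lack_of_fit_pct == pytest.approx(0.0)
        assert m.explained_variation_pct == pytest.approx(100.0)

    def test_full_residual(self):
        d = np.random.default_rng(0).random((3, 4))
        m = compute_metrics(d, d)
        assert m.lack_of_fit_pct == pytest.approx(100.0)
        assert m.explained_variation_pct == pytest.approx(0.0)

    def test_consistency_identity(self):
        # explained = 100 * (1 - (lof/100)^2); e.g. lof 6.711% => 99.5496%
        rng = np.random.default_rng(5)
        d = rng.random((4, 10)) + 1.0
        e = d * 0.06711
        m = compute_metrics(d, e)
        assert m.lack_of_fit_pct == pytest.approx(6.711, rel=1e-9)
        assert m.explained_variation_pct == pytest.approx(
            100.0 * (1.0 - (m.lack_of_fit_pct / 100.0) ** 2), rel=1e-12
        )
        assert m.explained_variation_pct == pytest.approx(99.5496, abs=1e-4)

    def test_zero_data_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((2, 2)), np.zeros((2, 2)))


class TestFitMcr:
    def test_rank1_exact(self):
        rng = np.random.default_rng(6)
        c = rng.random((12, 1)) + 0.2
        s = rng.random((1, 40)) + 0.1
        d = c @ s
        model, metrics = fit_mcr(d, MCRConfig(n_components=1))
        assert metrics.lack_of_fit_pct < 1e-6
        assert model.converged

    def test_rank1_matches_svd_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.random((10, 30)) + 0.5  # positive: leading pair is non-negative
        model, _ = fit_mcr(d, MCRConfig(n_components=1, conv_tol_pct=1e-6))
        u, sv, vt = np.linalg.svd(d)
        rank1 = sv[0] * np.outer(u[:, 0], vt[0])
        np.testing.assert_allclose(
            model.concentrations @ model.spectra, rank1, atol=1e-6
        )

    def test_noiseless_three_component_recovery(self, pure3_dataset):
        model, metrics = fit_mcr(
            pure3_dataset.spectra, MCRConfig(n_components=3, conv_tol_pct=1e-4)
        )
        spec_r, conc_r = matched_correlations(
            pure3_dataset.s_true, model.spectra,
            pure3_dataset.c_true, model.concentrations,
        )
        assert np.all(spec_r >= 0.999)
        assert np.all(conc_r >= 0.999)
        assert metrics.lack_of_fit_pct < 0.1

    def test_monotone_rss(self, small_cohort):
        model, _ = fit_mcr(small_cohort.spectra, MCRConfig(n_components=4, conv_tol_pct=1e-5))
        rss = np.array([t["rss"] for t in model.trace])
        assert np.all(np.diff(rss) <= 1e-9 * rss[:-1])

    def test_iteration_budget_and_flag_consistency(self, small_cohort):
        cfg = MCRConfig(n_components=4, max_iter=150, conv_tol_pct=0.1)
        model, _ = fit_mcr(small_cohort.spectra, cfg)
        assert model.n_iter_run <= 150
        assert len(model.trace) == model.n_iter_run
        if model.converged:
            sds = [t["residual_sd"] for t in model.trace]
            assert (
                sds[-1] <= 1e-12 * np.sqrt(np.mean(small_cohort.spectra.values**2))
                or abs(sds[-2] - sds[-1]) / sds[-2] * 100.0 <= 0.1
            )

    def test_free_rows_unit_sum(self, small_cohort):
        model, _ = fit_mcr(small_cohort.spectra, MCRConfig(n_components=4))
        np.testing.assert_allclose(model.spectra.sum(axis=1), 1.0, atol=1e-12)

    def test_nonneg_solution(self, small_cohort):
        model, _ = fit_mcr(small_cohort.spectra, MCRConfig(n_components=4))
        assert np.all(model.concentrations >= 0)
        assert np.all(model.spectra >= 0)

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            fit_mcr(np.zeros((5, 10)), MCRConfig(n_components=2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCRConfig(n_components=0)
        with pytest.raises(ValueError):
            MCRConfig(n_components=2, allowed_noise_pct=0.0)
        with pytest.raises(ValueError):
            MCRConfig(n_components=2, conv_tol_pct=0.0)
        with pytest.raises(ValueError):
            MCRConfig(n_components=3, fixed_spectra=np.ones((2, 5)))


class TestFitWithBasis:
    def test_regression_only_recovery(self, pure3_dataset):
        # basis = true spectra, no free components: pure NNLS regression
        model, _ = fit_with_basis(
            pure3_dataset.spectra, pure3_dataset.s_true, n_free=0,
            config=MCRConfig(n_components=3),
        )
        for k in range(3):
            r = np.corrcoef(pure3_dataset.c_true[:, k], model.concentrations[:, k])[0, 1]
            assert r >= 0.999

    def test_fixed_rows_byte_stable_and_free_rows_closed(self, small_cohort):
        basis = small_cohort.s_true  # 4 known spectra
        model, _ = fit_with_basis(
            small_cohort.spectra, basis, n_free=4,
            config=MCRConfig(n_components=8, max_iter=30),
        )
        basis_norm, _ = apply_closure(basis)
        assert np.array_equal(model.spectra[:4], basis_norm)
        assert model.fixed_mask.sum() == 4
        np.testing.assert_allclose(
            model.spectra[4:].sum(axis=1), 1.0, atol=1e-12
        )

    def test_eight_component_design(self, small_cohort):
        model, metrics = fit_with_basis(
            small_cohort.spectra, small_cohort.s_true, n_free=4,
            config=MCRConfig(n_components=8, max_iter=30),
        )
        assert model.spectra.shape[0] == 8
        assert metrics.lack_of_fit_pct < 5.0  # basis explains the clean data

    def test_negative_basis_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            fit_with_basis(small_cohort.spectra, -small_cohort.s_true, n_free=1)
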