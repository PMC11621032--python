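"""Posterior analysis: scaled speeds, periods, delays, point estimator."""

import numpy as np
import pytest

from circvelo.manifold import ManifoldFit
from circvelo.posterior import (
    PosteriorSamples,
    compare_conditions,
    delays,
    period,
    point_estimate_period,
    scaled_speed,
    test_nonzero as nonzero_speed_test,
)


def make_samples(omega_draws, log_gamma_value=None, n_genes=10, labels=None):
    omega_draws = np.asarray(omega_draws, dtype=float)
    if omega_draws.ndim == 1:
        omega_draws = omega_draws[:, None, None]
    n = omega_draws.shape[0]
    if log_gamma_value is None:
        log_gamma = np.zeros((n, n_genes))
    else:
        log_gamma = np.full((n, n_genes), log_gamma_value)
    return PosteriorSamples(
        nu_omega=omega_draws,
        log_beta=np.zeros((n, n_genes)),
        log_gamma=log_gamma,
        alpha_u=np.full((n, n_genes), 0.5),
        condition_labels=labels or ["all"] * 0 or ["all"],
    )


def fit_of_coeffs(nu, gene_ids=None):
    nu = np.atleast_2d(nu)
    return ManifoldFit(
        phi_xy_loc=np.zeros((1, 2)) + [1, 0],
        nu_loc=nu,
        nu_scale=np.zeros_like(nu),
        alpha_s=np.zeros(nu.shape[0]),
        delta_nu=np.zeros((1, nu.shape[0])),
        elbo_trace=np.asarray([]),
        gene_ids=gene_ids or [],
    )


class TestScaledSpeed:
    def test_unit_halflife(self):
        # all gamma = ln 2 -> physical half-life exactly 1 h
        s = scaled_speed(
            make_samples(np.full(100, 0.4), log_gamma_value=np.log(np.log(2))),
            mode="halflife",
        )
        np.testing.assert_allclose(s, 0.4)

    def test_doubling_gamma_halves_scaled_speed(self):
        s1 = scaled_speed(make_samples(np.full(10, 0.4), log_gamma_value=0.0))
        s2 = scaled_speed(make_samples(np.full(10, 0.4), log_gamma_value=np.log(2.0)))
        np.testing.assert_allclose(s1, 2 * s2)

    def test_recovery_within_band(self, small_velocity):
        s = scaled_speed(small_velocity.samples)
        assert np.mean(s) == pytest.approx(0.4, rel=0.25)


class TestPeriod:
    def test_constant_speed_closed_form(self):
        est = period(make_samples(np.full(500, 0.4)))
        assert est.mean == pytest.approx(2 * np.pi / 0.4, rel=1e-12)
        assert est.ci_hi - est.ci_lo == pytest.approx(0.0, abs=1e-9)

    def test_halflife_scaling(self):
        e1 = period(make_samples(np.full(10, 0.4)), mean_half_life_hours=1.0)
        e2 = period(make_samples(np.full(10, 0.4)), mean_half_life_hours=2.0)
        assert e2.mean == pytest.approx(2 * e1.mean)

    def test_periodic_speed_matches_dense_quadrature(self):
        coef = np.array([0.4, 0.1, 0.0])
        draws = np.tile(coef, (20, 1))[:, None, :]
        est = period(make_samples(draws))
        grid = np.linspace(0, 2 * np.pi, 10000)
        dense = np.trapezoid(1.0 / (0.4 + 0.1 * np.cos(grid)), grid)
        # 20-point trapezoid truncation error only
        assert est.mean == pytest.approx(dense, rel=5e-3)

    def test_nonpositive_draws_excluded(self):
        draws = np.concatenate([np.full(9, 0.4), [-0.1]])
        est = period(make_samples(draws))
        assert est.n_excluded == 1


class TestDelays:
    def test_simple_offset(self):
        # spliced peak at 1.3, unspliced at 1.0 -> delay +0.3
        fs = fit_of_coeffs([[0.0, np.cos(1.3), np.sin(1.3)]])
        fu = fit_of_coeffs([[0.0, np.cos(1.0), np.sin(1.0)]])
        tab = delays(fs, fu)
        assert tab.delay[0] == pytest.approx(0.3, abs=1e-9)

    def test_wrap_across_two_pi(self):
        fs = fit_of_coeffs([[0.0, np.cos(0.1), np.sin(0.1)]])
        fu = fit_of_coeffs([[0.0, np.cos(6.2), np.sin(6.2)]])
        tab = delays(fs, fu)
        assert tab.delay[0] == pytest.approx(0.1 - (6.2 - 2 * np.pi), abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        nu_a = np.column_stack([rng.normal(size=6), rng.normal(size=6), rng.normal(size=6)])
        nu_b = np.column_stack([rng.normal(size=6), rng.normal(size=6), rng.normal(size=6)])
        fa, fb = fit_of_coeffs(nu_a), fit_of_coeffs(nu_b)
        d1 = delays(fa, fb).delay
        d2 = delays(fb, fa).delay
        np.testing.assert_allclose(d1, -d2, atol=1e-9)

    def test_constant_gene_flagged(self):
        fs = fit_of_coeffs([[1.0, 0.0, 0.0]])
        fu = fit_of_coeffs([[1.0, 0.1, 0.0]])
        tab = delays(fs, fu)
        assert not tab.valid[0] and np.isnan(tab.delay[0])

    def test_tan_delay_relation_from_expectations(self):
        """Fit-free check of tan(delay) = omega/gamma on model curves."""
        from circvelo.core import KineticParams, expected_unspliced, fourier_basis

        omega, gamma, amp = 0.4, 1.2, 0.05
        nu_s = np.array([[1.0, amp, 0.0]])
        kin = KineticParams(np.array([0.0]), np.array([np.log(gamma)]))
        grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        u = expected_unspliced(grid, nu_s, kin, np.array([omega]))
        # project log u onto one harmonic to get its peak phase
        zeta = fourier_basis(grid, 1)
        coef, *_ = np.linalg.lstsq(zeta, np.log(u), rcond=None)
        fu = fit_of_coeffs(coef.T)
        fs = fit_of_coeffs(nu_s)
        tab = delays(fs, fu)
        assert np.tan(tab.delay[0]) == pytest.approx(omega / gamma, rel=0.02)


class TestPointEstimate:
    def test_exact_rank_one(self):
        delta = np.outer([0.5, 1.0], np.ones(10))
        omega_star, T_star = point_estimate_period(delta)
        np.testing.assert_allclose(omega_star, [0.5, 1.0], rtol=1e-12)
        np.testing.assert_allclose(T_star, [4 * np.pi, 2 * np.pi], rtol=1e-12)

    def test_orientation_mean_v_positive(self):
        delta = np.outer([-0.5, -1.0], -np.ones(8))
        omega_star, _ = point_estimate_period(delta)
        np.testing.assert_allclose(omega_star, [0.5, 1.0], rtol=1e-12)

    def test_noise_robustness_and_invariances(self):
        rng = np.random.default_rng(4)
        tau = rng.uniform(0.5, 1.5, 30)
        omega = np.array([0.3, 0.6, 0.9])
        delta = np.outer(omega, tau)
        noisy = delta + rng.normal(scale=0.01, size=delta.shape)
        w_hat, _ = point_estimate_period(noisy)
        w_ref, _ = point_estimate_period(delta)
        np.testing.assert_allclose(w_hat, w_ref, rtol=0.05)
        # gene permutation invariance
        perm = rng.permutation(30)
        w_perm, _ = point_estimate_period(delta[:, perm])
        np.testing.assert_allclose(w_perm, w_ref, rtol=1e-9)
        # duplicating gene columns leaves omega* unchanged
        w_dup, _ = point_estimate_period(np.hstack([delta, delta]))
        np.testing.assert_allclose(w_dup, w_ref, rtol=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            point_estimate_period(np.zeros((2, 5)))
        with pytest.raises(ValueError):
            point_estimate_period(np.ones((2, 1)))


class TestCredibility:
    def test_identical_conditions_overlap_fully(self):
        rng = np.random.default_rng(5)
        w = 0.4 + 0.05 * rng.standard_normal(500)
        draws = np.stack([w, w], axis=1)[:, :, None]
        samples = PosteriorSamples(
            nu_omega=draws,
            log_beta=np.zeros((500, 4)),
            log_gamma=np.zeros((500, 4)),
            alpha_u=np.zeros((500, 4)),
            condition_labels=["a", "b"],
        )
        rep = compare_conditions(samples, "a", "b")
        assert rep["overlap_fraction"] == pytest.approx(1.0)
        assert not rep["significant"]

    def test_separated_conditions_significant(self):
        rng = np.random.default_rng(6)
        draws = np.stack(
            [0.2 + 0.02 * rng.standard_normal(500), 0.8 + 0.02 * rng.standard_normal(500)],
            axis=1,
        )[:, :, None]
        samples = PosteriorSamples(
            nu_omega=draws,
            log_beta=np.zeros((500, 4)),
            log_gamma=np.zeros((500, 4)),
            alpha_u=np.zeros((500, 4)),
            condition_labels=["slow", "fast"],
        )
        rep = compare_conditions(samples, "slow", "fast")
        assert rep["significant"]
        assert rep["overlap_fraction"] < 0.05

    def test_nonzero_flags(self):
        rng = np.random.default_rng(7)
        strong = make_samples(0.4 + 0.02 * rng.standard_normal(500))
        null = make_samples(0.0 + 0.02 * rng.standard_normal(500))
        assert nonzero_speed_test(strong)["significant"]
        assert not nonzero_speed_test(null)["significant"]
        # interval exactly touching zero is not significant (strict exclusion)
        raw = np.linspace(0.0, 1.0, 500)
        touching = make_samples(raw - np.percentile(raw, 5))
        assert not nonzero_speed_test(touching)["significant"]
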