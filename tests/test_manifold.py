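"""Manifold learning: priors, conditioning, alignment, coverage, recovery."""

import numpy as np
import pytest

import circvelo as cv
from circvelo import manifold as mfl
from circvelo.simulate import circular_corrcoef


class TestInitPriors:
    def test_prior_mean_formulas(self, small_sim):
        data, _ = small_sim
        priors = mfl.init_priors(data)
        mean_s = data.S.mean(axis=0)
        np.testing.assert_allclose(
            priors.mu_nu[:, 0], np.log(np.maximum(mean_s, 1e-3))
        )
        assert np.all(priors.mu_nu[:, 1:] == 0)
        std = (data.S + 1.0).std(axis=0)
        np.testing.assert_allclose(priors.sigma_nu[:, 0], np.maximum(std, 0.01) / 2)
        np.testing.assert_allclose(priors.sigma_nu[:, 1], np.maximum(std, 0.01) / 4)

    def test_gene_with_mean_five(self):
        rng = np.random.default_rng(0)
        S = np.full((200, 1), 5)
        data = cv.CountDataset(S=S, U=rng.poisson(1, (200, 1)))
        priors = mfl.init_priors(data)
        assert priors.mu_nu[0, 0] == pytest.approx(np.log(5.0))
        # zero-variance gene: sd floored, priors stay proper
        assert np.all(priors.sigma_nu > 0)

    def test_phixy_prior_norm_is_epsilon(self, small_sim):
        data, _ = small_sim
        priors = mfl.init_priors(data)
        np.testing.assert_allclose(
            np.linalg.norm(priors.phixy_prior, axis=1), 5.0, rtol=1e-9
        )
        priors2 = mfl.init_priors(data, epsilon=2.0)
        np.testing.assert_allclose(
            np.linalg.norm(priors2.phixy_prior, axis=1), 2.0, rtol=1e-9
        )

    def test_rotation_maximizes_count_correlation(self, small_sim):
        """The chosen gauge beats (or ties) every grid alternative."""
        data, _ = small_sim
        priors = mfl.init_priors(data)
        Phi = np.arctan2(priors.phixy_prior[:, 1], priors.phixy_prior[:, 0])
        total = data.S.sum(axis=1).astype(float)

        def corr(x):
            return np.corrcoef(x, total)[0, 1]

        chosen = corr(np.mod(Phi, 2 * np.pi))
        rng_shifts = np.arange(0, 2 * np.pi, 2 * np.pi / 360)
        best = max(
            corr(np.mod(o * Phi + s, 2 * np.pi))
            for o in (1.0, -1.0)
            for s in rng_shifts
        )
        assert chosen >= best - 1e-9

    def test_empty_dataset_rejected(self):
        with pytest.raises(Exception):
            mfl.init_priors(cv.CountDataset(S=np.zeros((0, 3)), U=np.zeros((0, 3))))


class TestFitManifold:
    def test_recovery_small(self, small_sim, small_manifold):
        data, truth = small_sim
        cc = circular_corrcoef(small_manifold.phi_mean, truth.phi)
        assert cc >= 0.9

    def test_elbo_trace_finite_and_improving(self, small_manifold):
        tr = small_manifold.elbo_trace
        assert np.all(np.isfinite(tr))
        assert tr[-1] <= tr[0]

    def test_constant_genes_have_small_harmonics(self):
        """Genes simulated flat get first-harmonic posteriors consistent
        with zero while periodic genes anchor the phases."""
        from circvelo.simulate import sample_truth, sample_counts

        truth = sample_truth(600, 100, omega_gt=0.0, seed=4)
        flat = np.arange(60, 100)
        truth.nu[flat, 1:] = 0.0
        data = sample_counts(truth)
        priors = mfl.init_priors(data)
        fit = mfl.fit_manifold(data, priors, n_steps=1200, seed=4)
        z = np.abs(fit.nu_loc[flat, 1:]) / np.maximum(fit.nu_scale[flat, 1:], 1e-9)
        frac_consistent = np.mean((z < 2.0).all(axis=1))
        assert frac_consistent >= 0.9

    def test_conditioning_on_phi_is_identity(self, small_sim):
        data, truth = small_sim
        priors = mfl.init_priors(data)
        fit = mfl.fit_manifold(
            data, priors, n_steps=50, seed=0, condition_on={"phi": truth.phi}
        )
        np.testing.assert_allclose(fit.phi_mean, np.mod(truth.phi, 2 * np.pi))

    def test_conditioning_on_nu_freezes_harmonics(self, small_sim):
        data, truth = small_sim
        priors = mfl.init_priors(data)
        fit = mfl.fit_manifold(
            data, priors, n_steps=50, seed=0, condition_on={"nu": truth.nu}
        )
        np.testing.assert_array_equal(fit.nu_loc, truth.nu)
        assert np.all(fit.nu_scale == 0)

    def test_transfer_learning_recovers_phases(self, small_sim, small_manifold):
        """Harmonics learned on one replicate transfer to a second draw
        from the same truth."""
        from dataclasses import replace
        from circvelo.simulate import sample_counts

        data, truth = small_sim
        truth2 = replace(truth, seed=truth.seed + 500)
        data2 = sample_counts(truth2)
        priors2 = mfl.init_priors(data2)
        fit2 = mfl.fit_manifold(
            data2, priors2, n_steps=800, seed=7,
            condition_on={"nu": small_manifold.nu_loc},
        )
        fit2 = mfl.align_to_truth(fit2, truth2.phi)
        assert circular_corrcoef(fit2.phi_mean, truth2.phi) >= 0.9

    def test_transfer_learns_depth_offset(self, small_sim, small_manifold):
        """Conditioning on reference harmonics, a target dataset with
        doubled sequencing depth absorbs the difference into delta_nu."""
        rng = np.random.default_rng(13)
        data, truth = small_sim
        S2 = data.S + rng.binomial(data.S, 1.0)  # ~2x depth
        data2 = cv.CountDataset(S=S2, U=data.U)
        priors2 = mfl.init_priors(data2)
        fit2 = mfl.fit_manifold(
            data2, priors2, n_steps=800, seed=13,
            condition_on={"nu": small_manifold.nu_loc},
        )
        assert fit2.delta_nu.shape == (1, data.n_genes)
        # offset soaks up roughly log 2 relative to the depth the
        # reference harmonics encode
        ref_fit0 = mfl.fit_manifold(
            data, mfl.init_priors(data), n_steps=800, seed=13,
            condition_on={"nu": small_manifold.nu_loc},
        )
        shift = fit2.delta_nu[0].mean() - ref_fit0.delta_nu[0].mean()
        assert shift == pytest.approx(np.log(2.0), abs=0.2)

    def test_seed_stability_of_aligned_phases(self, small_sim):
        data, truth = small_sim
        priors = mfl.init_priors(data)
        f1 = mfl.fit_manifold(data, priors, n_steps=800, seed=10)
        f2 = mfl.fit_manifold(data, priors, n_steps=800, seed=20)
        f1 = mfl.align_to_truth(f1, truth.phi)
        f2 = mfl.align_to_truth(f2, truth.phi)
        assert circular_corrcoef(f1.phi_mean, f2.phi_mean) >= 0.95

    def test_batch_offset_learned(self):
        """A pure depth offset between two batches lands in delta_nu."""
        from circvelo.simulate import sample_truth, sample_counts

        truth = sample_truth(600, 50, omega_gt=0.0, seed=6)
        data = sample_counts(truth)
        S2 = data.S.copy()
        # second half of cells: double expression (offset log 2 on nu0)
        rng = np.random.default_rng(0)
        S2[300:] += rng.binomial(S2[300:], 1.0)  # ~doubling counts
        data2 = cv.CountDataset(
            S=S2, U=data.U, batch=np.array(["a"] * 300 + ["b"] * 300)
        )
        priors = mfl.init_priors(data2)
        fit = mfl.fit_manifold(
            data2, priors, n_steps=800, seed=6, condition_on={"phi": truth.phi}
        )
        assert fit.delta_nu.shape == (2, 50)
        assert np.all(fit.delta_nu[0] == 0)  # first batch pinned
        assert fit.delta_nu[1].mean() == pytest.approx(np.log(2.0), abs=0.15)


class TestAlignment:
    def test_identity_when_aligned(self, small_sim, small_manifold):
        data, truth = small_sim
        again = mfl.align_to_truth(small_manifold, truth.phi)
        np.testing.assert_allclose(
            again.phi_mean, small_manifold.phi_mean, atol=1e-6
        )

    def test_recovers_known_rotation(self, small_manifold):
        ref = np.mod(small_manifold.phi_mean + 1.0, 2 * np.pi)
        aligned = mfl.align_to_truth(small_manifold, ref)
        assert circular_corrcoef(aligned.phi_mean, ref) == pytest.approx(1.0, abs=1e-6)
        # rotation applied is +1 rad
        dev = np.angle(np.exp(1j * (aligned.phi_mean - small_manifold.phi_mean)))
        np.testing.assert_allclose(dev, 1.0, atol=1e-6)

    def test_detects_reflection(self, small_manifold):
        ref = np.mod(-small_manifold.phi_mean + 0.3, 2 * np.pi)
        aligned = mfl.align_to_truth(small_manifold, ref)
        assert circular_corrcoef(aligned.phi_mean, ref) == pytest.approx(1.0, abs=1e-6)

    def test_harmonics_transform_consistently(self, small_sim, small_manifold):
        """Rotating the fit leaves the expression surface unchanged."""
        from circvelo.core import expected_spliced

        data, _ = small_sim
        ref = np.mod(-small_manifold.phi_mean + 1.3, 2 * np.pi)
        aligned = mfl.align_to_truth(small_manifold, ref)
        s_orig = expected_spliced(small_manifold.phi_mean, small_manifold.nu_loc)
        s_new = expected_spliced(aligned.phi_mean, aligned.nu_loc)
        np.testing.assert_allclose(s_new, s_orig, rtol=1e-5)


class TestCoverage:
    def test_point_mass_at_truth_covers(self, small_sim):
        data, truth = small_sim
        fit = mfl.ManifoldFit(
            phi_xy_loc=np.stack([np.cos(truth.phi), np.sin(truth.phi)], 1),
            nu_loc=truth.nu,
            nu_scale=np.zeros_like(truth.nu),
            alpha_s=truth.alpha.alpha_s,
            delta_nu=np.zeros((1, data.n_genes)),
            elbo_trace=np.asarray([]),
            phi_fixed=truth.phi,
        )
        assert mfl.posterior_phase_coverage(fit, truth.phi) == 1.0

    def test_wide_posterior_covers_everything(self, small_sim):
        data, truth = small_sim
        # tiny location norm => nearly uniform posterior angles
        fit = mfl.ManifoldFit(
            phi_xy_loc=1e-6 * np.ones((data.n_cells, 2)),
            nu_loc=truth.nu,
            nu_scale=np.zeros_like(truth.nu),
            alpha_s=truth.alpha.alpha_s,
            delta_nu=np.zeros((1, data.n_genes)),
            elbo_trace=np.asarray([]),
        )
        cov = mfl.posterior_phase_coverage(fit, truth.phi)
        assert cov >= 0.85  # 5-95% band of a near-uniform posterior

    def test_calibration_on_fit(self, small_sim, small_manifold):
        data, truth = small_sim
        # rough calibration sanity at this small scale / short training;
        # full-scale calibration is checked in the acceptance suite
        cov = mfl.posterior_phase_coverage(small_manifold, truth.phi)
        assert cov >= 0.8
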