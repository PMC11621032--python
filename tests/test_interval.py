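"""B-spline interval model: basis properties and two-stage recovery."""

import numpy as np
import pytest

from circvelo.interval import (
    SplineBasis,
    bspline_basis,
    bspline_basis_derivative,
    fit_interval,
    simulate_interval,
)


@pytest.fixture(scope="module")
def basis():
    return SplineBasis()  # cubic, 5 basis functions on [0, 10]


class TestBasis:
    def test_partition_of_unity(self, basis):
        t = np.linspace(0.0, 10.0, 501)
        B = bspline_basis(t, basis)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(B >= 0)

    def test_order_zero_is_interval_indicator(self):
        b0 = SplineBasis(p=0, m=5, lo=0.0, hi=10.0)
        t = np.array([0.5, 2.5, 9.9])
        B = bspline_basis(t, b0)
        np.testing.assert_array_equal(B.sum(axis=1), 1.0)
        # each point activates exactly its knot interval
        assert np.array_equal(np.argmax(B, axis=1), np.array([0, 1, 4]))

    def test_matches_scipy_design_matrix(self, basis):
        """Independent oracle: scipy's BSpline design matrix."""
        from scipy.interpolate import BSpline

        t = np.linspace(0.0, 10.0, 173)
        ours = bspline_basis(t, basis)
        theirs = BSpline.design_matrix(t, basis.knots, basis.p).toarray()
        np.testing.assert_allclose(ours, theirs[:, : basis.m], atol=1e-12)

    def test_derivative_matches_finite_differences(self, basis):
        t = np.linspace(0.01, 9.99, 173)
        h = 1e-6
        fd = (bspline_basis(t + h, basis) - bspline_basis(t - h, basis)) / (2 * h)
        np.testing.assert_allclose(
            bspline_basis_derivative(t, basis), fd, atol=1e-5
        )

    def test_out_of_range_rejected(self, basis):
        with pytest.raises(ValueError):
            bspline_basis(np.array([-0.1]), basis)
        with pytest.raises(ValueError):
            bspline_basis_derivative(np.array([10.1]), basis)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            SplineBasis(knots=np.array([0.0, 1.0, 0.5, 2.0]))


class TestFit:
    @pytest.fixture(scope="class")
    def sim(self):
        # slope estimation noise attenuates omega on small datasets
        # (errors-in-variables); this size keeps the attenuation small
        return simulate_interval(2000, 150, omega_gt=0.5, seed=41)

    @pytest.fixture(scope="class")
    def fit(self, sim):
        data, truth = sim
        return fit_interval(data, truth.pseudotime, seed=41)

    def test_velocity_recovered(self, sim, fit):
        data, truth = sim
        assert fit.omega == pytest.approx(truth.omega, rel=0.25)

    def test_kinetic_ratio_recovered(self, sim, fit):
        data, truth = sim
        ratio_hat = np.exp(fit.kin.log_gamma - fit.kin.log_beta)
        ratio_true = np.exp(truth.kin.log_gamma - truth.kin.log_beta)
        assert np.corrcoef(ratio_hat, ratio_true)[0, 1] >= 0.9

    def test_spline_surface_positive_and_tracks_truth(self, sim, fit):
        data, truth = sim
        from circvelo.interval import bspline_basis as bb

        grid = np.linspace(0, 10, 50)
        B = bb(grid, fit.basis)
        logs_hat = B @ fit.w_loc.T
        logs_true = B @ truth.w.T
        r = np.corrcoef(logs_hat.ravel(), logs_true.ravel())[0, 1]
        assert r >= 0.95

    def test_zero_velocity_ratio_identity(self):
        data, truth = simulate_interval(2000, 20, omega_gt=0.0, seed=42)
        ratio = data.U.mean(axis=0) / np.maximum(data.S.mean(axis=0), 1e-9)
        expected = np.exp(truth.kin.log_gamma - truth.kin.log_beta)
        keep = data.S.mean(axis=0) > 0.5
        np.testing.assert_allclose(ratio[keep], expected[keep], rtol=0.25)

    def test_constant_gene_fits_flat_spline(self):
        data, truth = simulate_interval(500, 30, omega_gt=0.3, seed=43)
        # overwrite gene 0 counts with a constant-rate Poisson draw
        rng = np.random.default_rng(0)
        data.S[:, 0] = rng.poisson(4.0, size=500)
        fit = fit_interval(
            data, truth.pseudotime, n_steps_manifold=1000, n_steps_velocity=50,
            seed=43,
        )
        grid = np.linspace(0, 10, 50)
        curve = bspline_basis(grid, fit.basis) @ fit.w_loc[0]
        sd = np.max(fit.w_scale[0])
        assert curve.max() - curve.min() <= 4 * sd + 0.2

    def test_pseudotime_rescaled_with_warning(self, sim):
        data, truth = sim
        with pytest.warns(UserWarning, match="rescal"):
            fit_interval(
                data, truth.pseudotime * 3.0 - 5.0, n_steps_manifold=20,
                n_steps_velocity=20, seed=0,
            )

    def test_cross_model_consistency_on_half_cycle_arc(self):
        """Periodic-simulator data restricted to a half-cycle arc, fit with
        the interval model, recovers a speed consistent with the constant
        periodic-model speed (with pseudotime t = phi * 10/pi, the interval
        speed dt/dtime is ~ omega_gt * 10/pi)."""
        from circvelo.simulate import sample_dataset

        data, truth = sample_dataset(2500, 60, omega_gt=0.4, seed=44)
        arc = truth.phi < np.pi
        sub = data.subset_cells(arc)
        pt = truth.phi[arc] * 10.0 / np.pi
        fit = fit_interval(
            sub, pt, n_steps_manifold=1500, n_steps_velocity=3000, seed=44
        )
        expected = 0.4 * 10.0 / np.pi
        lo = fit.omega - 4 * fit.omega_sd
        hi = fit.omega + 4 * fit.omega_sd
        assert expected == pytest.approx(fit.omega, rel=0.35) or (lo <= expected <= hi)
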