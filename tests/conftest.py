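"""Shared fixtures: one small structured simulation with fits, reused widely.

Fixtures are session-scoped because the SVI fits, while small, take a few
seconds each; every test treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import circvelo as cv
from circvelo import manifold as mfl
from circvelo import velocity as vel


@pytest.fixture(scope="session")
def small_sim():
    """500 cells x 100 genes, constant truth speed 0.4."""
    data, truth = cv.sample_dataset(500, 100, omega_gt=0.4, seed=1)
    return data, truth


@pytest.fixture(scope="session")
def small_manifold(small_sim):
    data, truth = small_sim
    priors = mfl.init_priors(data)
    fit = mfl.fit_manifold(data, priors, n_steps=1200, seed=1)
    return mfl.align_to_truth(fit, truth.phi)


@pytest.fixture(scope="session")
def truth_manifold(small_sim):
    """A manifold 'fit' pinned at the simulation truth (for conditioning)."""
    data, truth = small_sim
    return mfl.ManifoldFit(
        phi_xy_loc=5.0 * np.stack([np.cos(truth.phi), np.sin(truth.phi)], axis=1),
        nu_loc=truth.nu,
        nu_scale=np.zeros_like(truth.nu),
        alpha_s=truth.alpha.alpha_s,
        delta_nu=np.zeros((1, data.n_genes)),
        elbo_trace=np.asarray([]),
        phi_fixed=truth.phi,
        gene_ids=list(data.gene_ids),
    )


@pytest.fixture(scope="session")
def small_velocity(small_sim, truth_manifold):
    data, _ = small_sim
    return vel.fit_velocity(data, truth_manifold, n_steps=3000, seed=1)


def make_truth_manifold(data, truth):
    """Helper mirroring the truth_manifold fixture for ad-hoc datasets."""
    return mfl.ManifoldFit(
        phi_xy_loc=5.0 * np.stack([np.cos(truth.phi), np.sin(truth.phi)], axis=1),
        nu_loc=truth.nu,
        nu_scale=np.zeros_like(truth.nu),
        alpha_s=truth.alpha.alpha_s,
        delta_nu=np.zeros((1, data.n_genes)),
        elbo_trace=np.asarray([]),
        phi_fixed=truth.phi,
        gene_ids=list(data.gene_ids),
    )
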