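"""Shared helper for the example scripts."""

import numpy as np

from circvelo import manifold as mfl


def truth_manifold(data, truth):
    """Manifold container pinned at the simulation truth, for conditioning
    the velocity stage on known phases/harmonics."""
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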