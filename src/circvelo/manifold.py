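"""Manifold learning: infer cell phases and gene harmonics from spliced counts.

The generative model for spliced counts is ``S_cg ~ NB(s_g(phi_c), alpha_g)``
with ``log s_g = zeta(phi) . nu_g`` (see :mod:`circvelo.core`).  The latent
per-cell phase is handled through a projected-normal construction: a 2-vector
``phixy_c`` with an isotropic unit-variance normal prior centred at
``epsilon * (cos Phi_c, sin Phi_c)``, where ``Phi_c`` is an empirical-Bayes
phase prior from the first two principal components of the spliced matrix and
``epsilon`` (default 5) acts as a concentration.  The phase is the angle of
the 2-vector.  The variational family is mean-field: unit-variance normals
with learned locations for ``phixy``, diagonal normals for ``nu``, point
masses for the dispersions and for the per-batch offsets ``delta_nu`` to the
zeroth harmonic.

The model is identifiable only up to a global rotation and reflection of the
circle; :func:`align_to_truth` resolves both against a reference phase
vector, and all circular-correlation bookkeeping assumes aligned fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from ._engine import (
    ClippedAdam,
    NBLikelihood,
    clip_logmu,
    gamma_logpdf,
    lr_schedule,
    normal_kl,
    normal_kl_grads,
    should_stop_early,
)
from .containers import CountDataset
from .core import fourier_basis, fourier_basis_derivative, n_basis, wrap_phase

__all__ = [
    "ManifoldPriors",
    "ManifoldFit",
    "init_priors",
    "fit_manifold",
    "align_to_truth",
    "posterior_phase_coverage",
]


def _wrap_to_pi(x: np.ndarray) -> np.ndarray:
    return np.mod(np.asarray(x) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class ManifoldPriors:
    """Empirical-Bayes priors for the manifold stage."""

    mu_nu: np.ndarray  # (genes, 2k+1)
    sigma_nu: np.ndarray  # (genes, 2k+1), positive
    phixy_prior: np.ndarray  # (cells, 2), rows of norm epsilon
    epsilon: float = 5.0
    alpha_prior: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if np.any(self.sigma_nu <= 0):
            raise ValueError("sigma_nu must be positive")

    @property
    def n_harmonics(self) -> int:
        return (self.mu_nu.shape[1] - 1) // 2


@dataclass
class ManifoldFit:
    """Variational posterior of the manifold stage."""

    phi_xy_loc: np.ndarray  # (cells, 2)
    nu_loc: np.ndarray  # (genes, 2k+1)
    nu_scale: np.ndarray  # (genes, 2k+1)
    alpha_s: np.ndarray  # (genes,)
    delta_nu: np.ndarray  # (batches, genes); first row pinned to zero
    elbo_trace: np.ndarray
    batch_labels: list = field(default_factory=lambda: ["all"])
    phi_fixed: np.ndarray | None = None  # set when phases were conditioned on
    gene_ids: list = field(default_factory=list)

    @property
    def phi_mean(self) -> np.ndarray:
        """Posterior point estimate of the phase, wrapped to [0, 2*pi)."""
        if self.phi_fixed is not None:
            return wrap_phase(self.phi_fixed)
        return wrap_phase(np.arctan2(self.phi_xy_loc[:, 1], self.phi_xy_loc[:, 0]))

    @property
    def n_harmonics(self) -> int:
        return (self.nu_loc.shape[1] - 1) // 2

    @property
    def n_cells(self) -> int:
        return self.phi_xy_loc.shape[0]

    def sample_phi(self, n_samples: int = 500, seed: int = 0) -> np.ndarray:
        """Posterior phase draws, shape (n_samples, cells)."""
        if self.phi_fixed is not None:
            return np.tile(wrap_phase(self.phi_fixed), (n_samples, 1))
        rng = np.random.default_rng(seed)
        xy = self.phi_xy_loc[None, :, :] + rng.standard_normal(
            (n_samples,) + self.phi_xy_loc.shape
        )
        return wrap_phase(np.arctan2(xy[..., 1], xy[..., 0]))

    def sample_nu(self, n_samples: int = 500, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.nu_loc[None] + self.nu_scale[None] * rng.standard_normal(
            (n_samples,) + self.nu_loc.shape
        )


def _pca_phase_prior(S: np.ndarray) -> np.ndarray:
    """Initial per-cell angle from the first two PCs of normalized counts."""
    depth = S.sum(axis=1, keepdims=True).astype(float)
    depth[depth == 0] = 1.0
    if S.shape[1] < 2:
        # degenerate: too few genes for a 2D embedding; rank-based fallback
        order = np.argsort(np.argsort(S.sum(axis=1)))
        return 2.0 * np.pi * order / S.shape[0]
    X = np.log1p(S / depth * np.median(depth))
    w = PCA(n_components=2, random_state=0).fit_transform(X)
    # renormalize each component to [-0.5, 0.5]
    lo, hi = w.min(axis=0), w.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    w = (w - lo) / span - 0.5
    return np.arctan2(w[:, 1], w[:, 0])


def _best_rotation(Phi: np.ndarray, total_counts: np.ndarray) -> np.ndarray:
    """Grid search over 360 shifts x 2 orientations maximizing
    Pearson corr(wrapped prior phase, total spliced counts)."""
    best = (-np.inf, None)
    tc = total_counts - total_counts.mean()
    tc_norm = np.sqrt((tc**2).sum())
    if tc_norm == 0:
        return wrap_phase(Phi)
    shifts = np.arange(360) * (2.0 * np.pi / 360.0)
    for orient in (1.0, -1.0):
        base = orient * Phi
        for sh in shifts:
            cand = wrap_phase(base + sh)
            cc = cand - cand.mean()
            denom = np.sqrt((cc**2).sum()) * tc_norm
            corr = float(cc @ tc / denom) if denom > 0 else -np.inf
            if corr > best[0]:
                best = (corr, cand)
    return best[1]


def init_priors(
    data: CountDataset,
    n_harmonics: int = 1,
    epsilon: float = 5.0,
    sigma_floor: float = 0.01,
) -> ManifoldPriors:
    """Empirical-Bayes priors from the spliced counts.

    Per gene: prior mean ``[log mean_c(S), 0, ..., 0]`` and prior sd
    ``[std_c(S+1)/2, std_c(S+1)/4, ...]`` (the higher harmonics all use the
    quarter-std).  Per cell: a unit 2-vector at the PCA-derived angle scaled
    by the concentration ``epsilon``, after fixing the rotational gauge by
    maximizing the correlation between the prior angle and total counts.
    """
    if data.n_cells == 0 or data.n_genes == 0:
        raise ValueError("dataset is empty")
    S = data.S.astype(float)
    mean_s = S.mean(axis=0)
    F = n_basis(n_harmonics)
    mu_nu = np.zeros((data.n_genes, F))
    mu_nu[:, 0] = np.log(np.maximum(mean_s, 1e-3))
    std_s = np.maximum((S + 1.0).std(axis=0), sigma_floor)
    sigma_nu = np.tile((std_s / 4.0)[:, None], (1, F))
    sigma_nu[:, 0] = std_s / 2.0
    Phi = _pca_phase_prior(data.S)
    Phi = _best_rotation(Phi, S.sum(axis=1))
    phixy = epsilon * np.stack([np.cos(Phi), np.sin(Phi)], axis=1)
    return ManifoldPriors(mu_nu=mu_nu, sigma_nu=sigma_nu, phixy_prior=phixy, epsilon=epsilon)


def fit_manifold(
    data: CountDataset,
    priors: ManifoldPriors | None = None,
    n_steps: int = 5000,
    seed: int = 0,
    condition_on: dict | None = None,
    lr_start: float = 0.03,
    lr_end: float = 0.005,
    early_stop: bool = False,
) -> ManifoldFit:
    """Fit the spliced-count model by SVI.

    ``condition_on`` may fix ``{"nu": array}`` (transfer learning: gene
    harmonics frozen, only phases, batch offsets and dispersions learned)
    and/or ``{"phi": array}`` (phases frozen, e.g. to fit unspliced
    harmonics at the spliced phases).
    """
    if priors is None:
        priors = init_priors(data)
    if priors.mu_nu.shape[0] != data.n_genes:
        raise ValueError("priors do not match the dataset gene count")
    condition_on = condition_on or {}
    C, G = data.n_cells, data.n_genes
    k = priors.n_harmonics
    F = n_basis(k)
    codes, labels = data.batch_codes()
    B = len(labels)
    rng = np.random.default_rng(seed)
    nb = NBLikelihood(data.S)
    a_shape, a_rate = priors.alpha_prior

    fixed_nu = condition_on.get("nu")
    fixed_phi = condition_on.get("phi")
    if fixed_nu is not None:
        fixed_nu = np.atleast_2d(np.asarray(fixed_nu, dtype=float))
        if fixed_nu.shape != (G, F):
            raise ValueError("conditioned nu has the wrong shape")
    if fixed_phi is not None:
        fixed_phi = np.asarray(fixed_phi, dtype=float).ravel()
        if fixed_phi.shape[0] != C:
            raise ValueError("conditioned phi has the wrong length")

    params: dict[str, np.ndarray] = {"a_alpha": np.full(G, np.log(a_shape / a_rate))}
    if fixed_phi is None:
        params["L"] = priors.phixy_prior.copy()
    if fixed_nu is None:
        params["M"] = priors.mu_nu.copy()
        params["P"] = np.full((G, F), np.log(0.1))
    # batch offsets: the first batch is pinned to zero for identifiability,
    # except under transfer learning (nu fixed externally), where every
    # batch of the target data learns its own offset against the reference
    n_pinned = 1 if fixed_nu is None else 0
    use_delta = (B - n_pinned) > 0
    if use_delta:
        params["delta"] = np.zeros((B - n_pinned, G))
    opt = ClippedAdam(params)
    batch_lists = [np.flatnonzero(codes == b) for b in range(B)]

    if fixed_phi is not None:
        zeta_fix = fourier_basis(fixed_phi, k).astype(np.float32)

    losses: list[float] = []
    for step in range(n_steps):
        p = opt.params
        grads: dict[str, np.ndarray] = {}
        alpha = np.exp(p["a_alpha"])
        r = 1.0 / np.maximum(alpha, 1e-12)

        if fixed_phi is None:
            eps_phi = rng.standard_normal((C, 2))
            xy = p["L"] + eps_phi
            phi = np.arctan2(xy[:, 1], xy[:, 0])
            zeta = fourier_basis(phi, k).astype(np.float32)
            dzeta = fourier_basis_derivative(phi, k).astype(np.float32)
        else:
            phi = fixed_phi
            zeta = zeta_fix
        if fixed_nu is None:
            eps_nu = rng.standard_normal((G, F))
            snu = np.exp(p["P"])
            nu = p["M"] + snu * eps_nu
        else:
            nu = fixed_nu

        nu32 = nu.astype(np.float32)
        logmu = zeta @ nu32.T
        if use_delta:
            delta_full = np.vstack(
                [np.zeros((n_pinned, G)), p["delta"]]
            ).astype(np.float32)
            logmu = logmu + delta_full[codes]
        logmu = clip_logmu(logmu)
        mu = np.exp(logmu)
        W, ll, g_r = nb.stats(mu, r)
        ll += nb.y_dot(logmu)

        grads["a_alpha"] = g_r * (-r) + ((a_shape - 1.0) - a_rate * alpha)
        kl = 0.0
        if fixed_nu is None:
            g_nu = (W.T @ zeta).astype(np.float64)
            knl, kns = normal_kl_grads(p["M"], p["P"], priors.mu_nu, priors.sigma_nu)
            grads["M"] = g_nu - knl
            grads["P"] = g_nu * eps_nu * snu - kns
            kl += normal_kl(p["M"], p["P"], priors.mu_nu, priors.sigma_nu)
        if fixed_phi is None:
            Q = W @ nu32  # (C, F)
            g_phi = np.einsum("cf,cf->c", Q, dzeta).astype(np.float64)
            rho2 = np.sum(xy**2, axis=1)
            g_x = -xy[:, 1] / rho2 * g_phi
            g_y = xy[:, 0] / rho2 * g_phi
            gL = np.stack([g_x, g_y], axis=1)
            gL -= p["L"] - priors.phixy_prior  # KL(N(L, I) || N(prior, I))
            grads["L"] = gL
            kl += 0.5 * float(np.sum((p["L"] - priors.phixy_prior) ** 2))
        if use_delta:
            g_delta = np.stack(
                [
                    W[cells].sum(axis=0, dtype=np.float64)
                    for cells in batch_lists[n_pinned:]
                ]
            )
            grads["delta"] = g_delta

        elbo = ll - kl + float(np.sum(gamma_logpdf(alpha, a_shape, a_rate)))
        if not np.isfinite(elbo):
            raise FloatingPointError(f"non-finite ELBO at manifold step {step}")
        losses.append(-elbo)
        opt.step(grads, lr_schedule(step, n_steps, lr_start, lr_end))
        if early_stop and should_stop_early(losses):
            break

    p = opt.params
    if fixed_phi is None:
        phi_xy_loc = p["L"]
        phi_fixed = None
    else:
        phi_xy_loc = priors.epsilon * np.stack(
            [np.cos(fixed_phi), np.sin(fixed_phi)], axis=1
        )
        phi_fixed = fixed_phi
    if fixed_nu is None:
        nu_loc, nu_scale = p["M"], np.exp(p["P"])
    else:
        nu_loc, nu_scale = fixed_nu, np.zeros_like(fixed_nu)
    delta = (
        np.vstack([np.zeros((n_pinned, G)), p["delta"]])
        if use_delta
        else np.zeros((B, G))
    )
    return ManifoldFit(
        phi_xy_loc=phi_xy_loc,
        nu_loc=nu_loc,
        nu_scale=nu_scale,
        alpha_s=np.exp(p["a_alpha"]),
        delta_nu=delta,
        elbo_trace=np.asarray(losses),
        batch_labels=labels,
        phi_fixed=phi_fixed,
        gene_ids=list(data.gene_ids),
    )


def _transform_nu(nu: np.ndarray, rotation: float, orientation: float) -> np.ndarray:
    """Re-express gene harmonics in the rotated/reflected phase coordinate.

    If ``phi_new = orientation * phi + rotation`` then for each harmonic j
    the (cos, sin) pair transforms by a rotation of angle ``j * rotation``
    after flipping the sine coefficient under reflection.
    """
    nu = np.atleast_2d(nu).copy()
    k = (nu.shape[1] - 1) // 2
    for j in range(1, k + 1):
        a = nu[:, 2 * j - 1].copy()
        b = orientation * nu[:, 2 * j].copy()
        cj, sj = np.cos(j * rotation), np.sin(j * rotation)
        nu[:, 2 * j - 1] = a * cj - b * sj
        nu[:, 2 * j] = a * sj + b * cj
    return nu


def align_to_truth(
    fit: ManifoldFit, phi_ref: np.ndarray, mask: np.ndarray | None = None
) -> ManifoldFit:
    """Resolve the global rotation/reflection gauge against reference phases.

    Chooses orientation o in {+1, -1} and rotation rho maximizing the
    circular correlation of ``o * phi + rho`` with ``phi_ref`` (the modulus
    is rotation-invariant, so the optimal rotation has the closed form
    ``-arg mean(exp(i (o*phi - phi_ref)))``).  Gene harmonics, phase
    locations and (if present) fixed phases are transformed consistently.
    When ``mask`` is given, only the masked cells inform the gauge (e.g.
    the cycling subpopulation of a contaminated mixture) but the whole fit
    is transformed.
    """
    phi_ref = np.asarray(phi_ref, dtype=float).ravel()
    phi = fit.phi_mean
    sel = slice(None) if mask is None else np.asarray(mask)
    if phi_ref[sel].shape[0] != phi[sel].shape[0]:
        raise ValueError("reference phases must match the fitted cell count")
    best = None
    for orient in (1.0, -1.0):
        z = np.mean(np.exp(1j * (orient * phi[sel] - phi_ref[sel])))
        rot = float(-np.angle(z))
        score = float(np.abs(z))
        if best is None or score > best[0] + 1e-12:
            best = (score, orient, rot)
    _, orient, rot = best
    cr, sr = np.cos(rot), np.sin(rot)
    xy = fit.phi_xy_loc.copy()
    if orient < 0:
        xy[:, 1] = -xy[:, 1]
    rot_mat = np.array([[cr, -sr], [sr, cr]])
    xy = xy @ rot_mat.T
    return ManifoldFit(
        phi_xy_loc=xy,
        nu_loc=_transform_nu(fit.nu_loc, rot, orient),
        nu_scale=fit.nu_scale.copy(),
        alpha_s=fit.alpha_s.copy(),
        delta_nu=fit.delta_nu.copy(),
        elbo_trace=fit.elbo_trace.copy(),
        batch_labels=list(fit.batch_labels),
        phi_fixed=None
        if fit.phi_fixed is None
        else wrap_phase(orient * fit.phi_fixed + rot),
        gene_ids=list(fit.gene_ids),
    )


def posterior_phase_coverage(
    fit: ManifoldFit,
    phi_true: np.ndarray,
    lo: float = 5.0,
    hi: float = 95.0,
    n_samples: int = 500,
    seed: int = 0,
) -> float:
    """Fraction of cells whose true phase lies in the posterior interval.

    Per cell, posterior draws are wrapped around the posterior mean phase
    and the ``lo``-``hi`` percentile band of the wrapped deviations forms a
    circular credible interval.  ``fit`` must already be aligned to
    ``phi_true`` (see :func:`align_to_truth`).
    """
    phi_true = np.asarray(phi_true, dtype=float).ravel()
    draws = fit.sample_phi(n_samples=n_samples, seed=seed)
    center = fit.phi_mean
    dev = _wrap_to_pi(draws - center[None, :])
    q_lo = np.percentile(dev, lo, axis=0)
    q_hi = np.percentile(dev, hi, axis=0)
    true_dev = _wrap_to_pi(phi_true - center)
    return float(np.mean((true_dev >= q_lo) & (true_dev <= q_hi)))
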