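"""1D nonperiodic extension: B-spline manifold over a fixed pseudotime.

Proof-of-principle variant of the two-stage model for processes that unfold
along an interval (for example a differentiation trajectory) rather than a
circle.  The Fourier series is replaced by a cubic B-spline basis

    log s_g(t) = sum_f w_gf B_{3,f}(t),

built by the Cox-de Boor recursion on a clamped uniform knot vector over
the pseudotime range (default [0, 10], basis dimension 5), and the velocity
is a single scalar, constant along the process.  Pseudotime is an input
(computed upstream, e.g. by a diffusion map); this module never derives it.

Stage 1 fits the spline coefficients from spliced counts conditioned on
pseudotime; stage 2 fits (beta, gamma, alpha, omega) from unspliced counts
with the spline surface frozen, through exactly the same machinery as the
periodic model:

    log u_g(t) = -log beta_g + log( omega * sum_f w_gf dB_{3,f}/dt + gamma_g )
                 + log s_g(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._engine import (
    ClippedAdam,
    NBLikelihood,
    clip_logmu,
    fit_velocity_core,
    gamma_logpdf,
    lr_schedule,
    normal_kl,
    normal_kl_grads,
)
from .containers import CountDataset
from .core import KineticParams, NoiseParams, RELU_FLOOR
from .posterior import PosteriorSamples
from .simulate import TruthConfig, _nb_sample

__all__ = [
    "SplineBasis",
    "IntervalFit",
    "bspline_basis",
    "bspline_basis_derivative",
    "simulate_interval",
    "fit_interval",
]


@dataclass
class SplineBasis:
    """Clamped B-spline basis of order ``p`` with ``m`` basis functions.

    The knot vector has ``m + p + 1`` entries: the first and last knots are
    repeated ``p + 1`` times (clamping) so the basis spans the closed
    interval and sums to one everywhere inside it.
    """

    p: int = 3
    m: int = 5
    lo: float = 0.0
    hi: float = 10.0
    knots: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.m < self.p + 1:
            raise ValueError("basis dimension must be at least order + 1")
        if self.knots is None:
            n_interior = self.m - self.p - 1
            interior = np.linspace(self.lo, self.hi, n_interior + 2)[1:-1]
            self.knots = np.concatenate(
                [np.full(self.p + 1, self.lo), interior, np.full(self.p + 1, self.hi)]
            )
        self.knots = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be nondecreasing")
        if self.knots.size != self.m + self.p + 1:
            raise ValueError("knot vector must have m + p + 1 entries")


def _bspline_cols(t: np.ndarray, knots: np.ndarray, p: int, m: int) -> np.ndarray:
    """Cox-de Boor recursion, vectorized over evaluation points.

    Base case: indicator of the half-open knot interval [t_i, t_{i+1}),
    closed at the global right endpoint so the clamped basis keeps its
    partition of unity on the full closed interval.
    """
    n0 = knots.size - 1
    B = np.zeros((t.size, n0))
    hi = knots[-1]
    for i in range(n0):
        if knots[i + 1] > knots[i]:
            inside = (t >= knots[i]) & (t < knots[i + 1])
            if knots[i + 1] == hi:
                inside |= t == hi
            B[:, i] = inside.astype(float)
    for q in range(1, p + 1):
        Bq = np.zeros((t.size, n0 - q))
        for i in range(n0 - q):
            left_den = knots[i + q] - knots[i]
            right_den = knots[i + q + 1] - knots[i + 1]
            term = 0.0
            if left_den > 0:
                term = (t - knots[i]) / left_den * B[:, i]
            if right_den > 0:
                term = term + (knots[i + q + 1] - t) / right_den * B[:, i + 1]
            Bq[:, i] = term
        B = Bq
    return B[:, :m]


def bspline_basis(t: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Design matrix of shape (points, m); errors for t outside the knots."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < basis.knots[0]) or np.any(t > basis.knots[-1]):
        raise ValueError("evaluation points fall outside the knot range")
    return _bspline_cols(t, basis.knots, basis.p, basis.m)


def bspline_basis_derivative(t: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Derivative of each basis function: the standard order-reduction formula
    ``B'_{p,i} = p/(t_{i+p}-t_i) B_{p-1,i} - p/(t_{i+p+1}-t_{i+1}) B_{p-1,i+1}``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < basis.knots[0]) or np.any(t > basis.knots[-1]):
        raise ValueError("evaluation points fall outside the knot range")
    p, knots = basis.p, basis.knots
    if p == 0:
        return np.zeros((t.size, basis.m))
    Blow = _bspline_cols(t, knots, p - 1, knots.size - p)
    out = np.zeros((t.size, basis.m))
    for i in range(basis.m):
        left_den = knots[i + p] - knots[i]
        right_den = knots[i + p + 1] - knots[i + 1]
        if left_den > 0:
            out[:, i] += p / left_den * Blow[:, i]
        if right_den > 0:
            out[:, i] -= p / right_den * Blow[:, i + 1]
    return out


@dataclass
class IntervalFit:
    """Two-stage fit of the interval model."""

    w_loc: np.ndarray  # (genes, m) spline coefficients
    w_scale: np.ndarray
    kin: KineticParams
    kin_sd: KineticParams
    omega: float
    omega_sd: float
    alpha_s: np.ndarray
    alpha_u: np.ndarray
    basis: SplineBasis
    pseudotime: np.ndarray
    samples: PosteriorSamples | None = None
    elbo_trace_manifold: np.ndarray | None = None
    elbo_trace_velocity: np.ndarray | None = None


@dataclass
class IntervalTruth:
    pseudotime: np.ndarray
    w: np.ndarray
    kin: KineticParams
    omega: float
    alpha: NoiseParams
    seed: int


def simulate_interval(
    n_cells: int,
    n_genes: int,
    omega_gt: float = 0.5,
    seed: int = 0,
    basis: SplineBasis | None = None,
    config: TruthConfig | None = None,
) -> tuple[CountDataset, IntervalTruth]:
    """Simulate counts along an interval with constant scalar velocity.

    Reuses the correlated coefficient scheme of the periodic simulator:
    the per-gene 5-vector (level, amp1, amp2, log beta, log gamma) is drawn
    from the same multivariate normal, and the spline coefficients are
    ``w_gf = level_g + amp1_g * ramp_f + amp2_g * bump_f`` with fixed
    smooth ramp/bump patterns, giving monotone and transient gene programs.
    """
    basis = basis or SplineBasis()
    config = config or TruthConfig()
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        config.means(), config.covariance_matrix(), size=n_genes, method="cholesky"
    )
    m = basis.m
    ramp = np.linspace(-1.0, 1.0, m)
    bump = np.exp(-0.5 * ((np.arange(m) - (m - 1) / 2) / (m / 4.0)) ** 2)
    bump = bump - bump.mean()
    w = draws[:, 0:1] + draws[:, 1:2] * ramp[None, :] + draws[:, 2:3] * bump[None, :]
    kin = KineticParams(log_beta=draws[:, 3], log_gamma=draws[:, 4])
    alpha = NoiseParams(
        alpha_s=rng.gamma(config.alpha_shape, 1.0 / config.alpha_rate, size=n_genes),
        alpha_u=rng.gamma(config.alpha_shape, 1.0 / config.alpha_rate, size=n_genes),
    )
    t = rng.uniform(basis.lo, basis.hi, size=n_cells)
    B = bspline_basis(t, basis)
    dB = bspline_basis_derivative(t, basis)
    logs = B @ w.T
    s_mean = np.exp(logs)
    inner = np.maximum(omega_gt * (dB @ w.T) + kin.gamma[None, :], RELU_FLOOR)
    u_mean = s_mean / kin.beta[None, :] * inner
    S = _nb_sample(rng, s_mean, alpha.alpha_s)
    U = _nb_sample(rng, u_mean, alpha.alpha_u)
    data = CountDataset(S=S, U=U)
    return data, IntervalTruth(
        pseudotime=t, w=w, kin=kin, omega=float(omega_gt), alpha=alpha, seed=seed
    )


def _fit_spline_stage(
    S: np.ndarray,
    B32: np.ndarray,
    prior_sd: float,
    n_steps: int,
    seed: int,
    alpha_prior: tuple[float, float] = (1.0, 2.0),
):
    """Fit spline coefficients with a normal guide (pseudotime fixed)."""
    rng = np.random.default_rng(seed)
    C, G = S.shape
    m = B32.shape[1]
    nb = NBLikelihood(S)
    a_shape, a_rate = alpha_prior
    params = {
        "M": np.zeros((G, m)),
        "P": np.full((G, m), np.log(0.1)),
        "a_alpha": np.full(G, np.log(a_shape / a_rate)),
    }
    opt = ClippedAdam(params)
    losses: list[float] = []
    for step in range(n_steps):
        p = opt.params
        alpha = np.exp(p["a_alpha"])
        r = 1.0 / np.maximum(alpha, 1e-12)
        eps = rng.standard_normal((G, m))
        sw = np.exp(p["P"])
        wcoef = p["M"] + sw * eps
        logmu = clip_logmu(B32 @ wcoef.T.astype(np.float32))
        mu = np.exp(logmu)
        W, ll, g_r = nb.stats(mu, r)
        ll += nb.y_dot(logmu)
        g_w = (W.T @ B32).astype(np.float64)
        kl_l, kl_s = normal_kl_grads(p["M"], p["P"], 0.0, prior_sd)
        grads = {
            "M": g_w - kl_l,
            "P": g_w * eps * sw - kl_s,
            "a_alpha": g_r * (-r) + (a_shape - 1.0) - a_rate * alpha,
        }
        elbo = (
            ll
            - normal_kl(p["M"], p["P"], 0.0, prior_sd)
            + float(np.sum(gamma_logpdf(alpha, a_shape, a_rate)))
        )
        if not np.isfinite(elbo):
            raise FloatingPointError(f"non-finite ELBO at spline step {step}")
        losses.append(-elbo)
        opt.step(grads, lr_schedule(step, n_steps))
    return opt.params, losses


def fit_interval(
    data: CountDataset,
    pseudotime: np.ndarray,
    basis: SplineBasis | None = None,
    n_steps_manifold: int = 2000,
    n_steps_velocity: int = 6000,
    seed: int = 0,
    spline_prior_sd: float = 3.0,
    omega_prior_sd: float = 3.0,
    n_posterior_samples: int = 500,
) -> IntervalFit:
    """Two-stage fit along a supplied pseudotime coordinate.

    Pseudotime is expected on [0, 10]; values outside are linearly rescaled
    with a warning.  The speed prior is a single broad normal N(0, sd^2).
    """
    basis = basis or SplineBasis()
    t = np.asarray(pseudotime, dtype=float).ravel()
    if t.shape[0] != data.n_cells:
        raise ValueError("pseudotime length must match the cell count")
    if t.min() < basis.lo or t.max() > basis.hi:
        warnings.warn("pseudotime outside [lo, hi]; rescaling", UserWarning)
        t = basis.lo + (t - t.min()) / (t.max() - t.min()) * (basis.hi - basis.lo)
    B = bspline_basis(t, basis)
    dB = bspline_basis_derivative(t, basis)
    params_m, losses_m = _fit_spline_stage(
        data.S, B.astype(np.float32), spline_prior_sd, n_steps_manifold, seed
    )
    w = params_m["M"]
    logs = B @ w.T
    D = dB @ w.T
    res = fit_velocity_core(
        data.U,
        logs,
        D,
        np.ones((data.n_cells, 1)),
        np.zeros(data.n_cells, dtype=int),
        1,
        guide="meanfield",
        n_steps=n_steps_velocity,
        seed=seed + 1,
        prior_nu_omega_sd=np.array([omega_prior_sd]),
    )
    p = res.params
    rng = np.random.default_rng(seed + 2)
    n = n_posterior_samples
    G = data.n_genes
    samples = PosteriorSamples(
        nu_omega=(p["m_omega"][None] + np.exp(p["p_omega"])[None]
                  * rng.standard_normal((n, 1, 1))),
        log_beta=p["m_beta"] + np.exp(p["p_beta"]) * rng.standard_normal((n, G)),
        log_gamma=p["m_gamma"] + np.exp(p["p_gamma"]) * rng.standard_normal((n, G)),
        alpha_u=np.tile(np.exp(p["a_alpha"])[None], (n, 1)),
    )
    return IntervalFit(
        w_loc=w,
        w_scale=np.exp(params_m["P"]),
        kin=KineticParams(p["m_beta"], p["m_gamma"]),
        kin_sd=KineticParams(np.exp(p["p_beta"]), np.exp(p["p_gamma"])),
        omega=float(p["m_omega"][0, 0]),
        omega_sd=float(np.exp(p["p_omega"][0, 0])),
        alpha_s=np.exp(params_m["a_alpha"]),
        alpha_u=np.exp(p["a_alpha"]),
        basis=basis,
        pseudotime=t,
        samples=samples,
        elbo_trace_manifold=np.asarray(losses_m),
        elbo_trace_velocity=np.asarray(res.losses),
    )
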