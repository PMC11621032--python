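"""Deterministic mathematical core of the circular velocity model.

The cell cycle is represented as a one-dimensional periodic manifold: every
cell sits at an angular coordinate (phase) ``phi`` on the unit circle, and the
expected spliced expression of gene ``g`` is a log-linear Fourier series in
that phase,

    log s_g(phi) = sum_f nu_gf * zeta_f(phi),

with ``zeta(phi) = (1, cos phi, sin phi, ..., cos k*phi, sin k*phi)``.  The
speed at which cells progress around the circle is a (possibly constant)
Fourier series ``omega(phi) = nu_omega . zeta(phi)`` in *linear* (not log)
parametrization.  Combining the splicing/degradation rate equation

    d s_g / dt = beta_g * u_g - gamma_g * s_g

with the chain rule ``d s_g / dt = omega(phi) * d s_g / d phi`` yields the
expected unspliced expression

    u_g(phi) = s_g(phi) / beta_g * relu( omega(phi) * sum_f nu_gf *
               d/dphi zeta_f(phi) + gamma_g ),

where the relu keeps the negative-binomial mean positive wherever the inner
term would transiently dip below zero.  These functions are shared verbatim
by the simulator and by both inference stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RELU_FLOOR",
    "KineticParams",
    "NoiseParams",
    "wrap_phase",
    "n_basis",
    "harmonics_of",
    "fourier_basis",
    "fourier_basis_derivative",
    "expected_spliced",
    "angular_speed",
    "expected_unspliced",
]

#: Lower clamp applied to the inner (pre-log) term of the unspliced mean so
#: that the log-likelihood stays finite while gradients remain informative.
RELU_FLOOR = 1e-5


@dataclass
class KineticParams:
    """Per-gene first-order kinetic rates, stored on the log scale.

    ``beta`` is the splicing rate and ``gamma`` the degradation rate, both in
    1/h.  Only their ratio (and their scale relative to the angular speed) is
    identifiable from spliced/unspliced count ratios.
    """

    log_beta: np.ndarray
    log_gamma: np.ndarray

    def __post_init__(self) -> None:
        self.log_beta = np.asarray(self.log_beta, dtype=float)
        self.log_gamma = np.asarray(self.log_gamma, dtype=float)
        if self.log_beta.shape != self.log_gamma.shape:
            raise ValueError("log_beta and log_gamma must have the same shape")
        if not (np.all(np.isfinite(self.log_beta)) and np.all(np.isfinite(self.log_gamma))):
            raise ValueError("kinetic parameters must be finite")

    @property
    def beta(self) -> np.ndarray:
        return np.exp(self.log_beta)

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma)

    @property
    def n_genes(self) -> int:
        return self.log_beta.shape[0]


@dataclass
class NoiseParams:
    """Per-gene negative-binomial dispersions (inverse shape).

    ``alpha = 0`` degenerates to a Poisson noise model; the per-entry count
    variance is ``mu + alpha * mu**2``.
    """

    alpha_s: np.ndarray
    alpha_u: np.ndarray

    def __post_init__(self) -> None:
        self.alpha_s = np.asarray(self.alpha_s, dtype=float)
        self.alpha_u = np.asarray(self.alpha_u, dtype=float)
        if np.any(self.alpha_s < 0) or np.any(self.alpha_u < 0):
            raise ValueError("dispersions must be nonnegative")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the canonical interval ``[0, 2*pi)``."""
    phi = np.asarray(phi, dtype=float)
    return np.mod(phi, 2.0 * np.pi)


def n_basis(k: int) -> int:
    """Number of Fourier basis functions for ``k`` harmonics (``2k + 1``)."""
    if k < 0:
        raise ValueError(f"harmonic count must be nonnegative, got {k}")
    return 2 * int(k) + 1


def harmonics_of(nu: np.ndarray) -> int:
    """Infer the harmonic count ``k`` from a coefficient row length ``2k+1``."""
    ncol = np.atleast_2d(nu).shape[1]
    if ncol % 2 != 1:
        raise ValueError(f"coefficient rows must have odd length 2k+1, got {ncol}")
    return (ncol - 1) // 2


def fourier_basis(phi: np.ndarray, k: int = 1) -> np.ndarray:
    """Circular Fourier design matrix ``zeta(phi)``, shape (cells, 2k+1).

    Columns are ordered ``[1, cos(phi), sin(phi), ..., cos(k phi), sin(k phi)]``.
    """
    if k < 0:
        raise ValueError(f"harmonic count must be nonnegative, got {k}")
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    cols = [np.ones_like(phi)]
    for j in range(1, k + 1):
        cols.append(np.cos(j * phi))
        cols.append(np.sin(j * phi))
    return np.stack(cols, axis=-1)


def fourier_basis_derivative(phi: np.ndarray, k: int = 1) -> np.ndarray:
    """Entrywise derivative of :func:`fourier_basis` with respect to phase."""
    if k < 0:
        raise ValueError(f"harmonic count must be nonnegative, got {k}")
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    cols = [np.zeros_like(phi)]
    for j in range(1, k + 1):
        cols.append(-j * np.sin(j * phi))
        cols.append(j * np.cos(j * phi))
    return np.stack(cols, axis=-1)


def expected_spliced(phi: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Expected spliced counts ``s_g(phi_c)``, shape (cells, genes).

    ``nu`` has one row per gene, ordered ``[a0, a1, b1, ..., ak, bk]``; the
    output is ``exp(zeta(phi) @ nu.T)`` and therefore strictly positive.
    """
    nu = np.atleast_2d(np.asarray(nu, dtype=float))
    if not np.all(np.isfinite(nu)):
        raise ValueError("Fourier coefficients must be finite")
    k = harmonics_of(nu)
    basis = fourier_basis(phi, k)
    return np.exp(basis @ nu.T)


def angular_speed(phi: np.ndarray, nu_omega: np.ndarray) -> np.ndarray:
    """Angular speed ``omega(phi_c)`` per cell, in radians per unit time.

    ``nu_omega`` is a coefficient vector in the *linear* Fourier
    parametrization; a length-1 vector is the constant-speed model and is
    broadcast to every cell.  The series may be locally negative; positivity
    of the unspliced mean is enforced downstream by the relu.
    """
    nu_omega = np.asarray(nu_omega, dtype=float).ravel()
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if nu_omega.size == 1:
        return np.full(phi.shape, nu_omega[0])
    k = harmonics_of(nu_omega[None, :])
    return fourier_basis(phi, k) @ nu_omega


def expected_unspliced(
    phi: np.ndarray,
    nu: np.ndarray,
    kin: KineticParams,
    nu_omega: np.ndarray,
    floor: float = RELU_FLOOR,
) -> np.ndarray:
    """Expected unspliced counts ``u_g(phi_c)``, shape (cells, genes).

    Implements ``u = s/beta * relu(omega * sum_f nu_gf dzeta_f + gamma)``
    with the relu realized as a clamp at ``floor`` (so the log of the output
    is always finite).  With ``omega == 0`` this reduces exactly to
    ``u = s * gamma / beta``.
    """
    nu = np.atleast_2d(np.asarray(nu, dtype=float))
    if not np.all(np.isfinite(nu)):
        raise ValueError("Fourier coefficients must be finite")
    k = harmonics_of(nu)
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    s = expected_spliced(phi, nu)
    dzeta = fourier_basis_derivative(phi, k)
    slope = dzeta @ nu.T  # (cells, genes): d/dphi log s
    omega = angular_speed(phi, nu_omega)
    inner = omega[:, None] * slope + kin.gamma[None, :]
    inner = np.maximum(inner, floor)
    return s / kin.beta[None, :] * inner
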