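"""Minimal No-U-Turn sampler with dual-averaging step-size adaptation.

Used as the MCMC backend of the velocity stage.  This is a compact
implementation of the standard recursive tree-doubling NUTS algorithm with
a diagonal mass matrix (taken from the SVI posterior scales, which makes
identity-mass preconditioning adequate at the problem sizes used here).
"""

from __future__ import annotations

import numpy as np

__all__ = ["nuts_sample"]

_MAX_ENERGY_ERROR = 1000.0


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "grad_prop", "logp_prop",
        "n_valid", "keep_going", "alpha", "n_alpha", "divergent",
    )


def _leapfrog(f, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp1, grad1 = f(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, grad1, logp1


def _hamiltonian(logp, r, inv_mass):
    return logp - 0.5 * float(np.sum(inv_mass * r * r))


def nuts_sample(
    f,
    x0: np.ndarray,
    n_warmup: int = 2000,
    n_samples: int = 500,
    seed: int = 0,
    inv_mass_diag: np.ndarray | None = None,
    max_depth: int = 8,
    target_accept: float = 0.8,
):
    """Draw samples from ``exp(logp)`` where ``f(x) -> (logp, grad)``.

    Returns ``(samples, diagnostics)`` with diagnostics holding the number
    of divergent transitions and the adapted step size.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(x0, dtype=float).copy()
    dim = theta.size
    inv_mass = (
        np.ones(dim) if inv_mass_diag is None else np.asarray(inv_mass_diag, dtype=float)
    )
    mass_sd = 1.0 / np.sqrt(inv_mass)
    logp, grad = f(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")

    # reasonable initial step size
    eps = 0.1
    r0 = rng.standard_normal(dim) * mass_sd
    _, r1, _, logp1 = _leapfrog(f, theta, r0, grad, eps, inv_mass)
    joint0 = _hamiltonian(logp, r0, inv_mass)
    joint1 = _hamiltonian(logp1, r1, inv_mass)
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    while True:
        candidate = eps * (2.0**direction)
        if candidate < 1e-8 or candidate > 1e3:
            break
        eps = candidate
        _, r1, _, logp1 = _leapfrog(f, theta, r0, grad, eps, inv_mass)
        joint1 = _hamiltonian(logp1, r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break

    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75

    samples = np.empty((n_samples, dim))
    n_divergent = 0

    def build_tree(theta, r, grad, logu, v, j, eps, joint0):
        tree = _Tree()
        if j == 0:
            theta1, r1, grad1, logp1 = _leapfrog(f, theta, r, grad, v * eps, inv_mass)
            joint = _hamiltonian(logp1, r1, inv_mass)
            tree.divergent = (not np.isfinite(joint)) or (logu - joint > _MAX_ENERGY_ERROR)
            tree.n_valid = int(logu <= joint)
            tree.keep_going = not tree.divergent
            tree.theta_minus = tree.theta_plus = tree.theta_prop = theta1
            tree.r_minus = tree.r_plus = r1
            tree.grad_minus = tree.grad_plus = tree.grad_prop = grad1
            tree.logp_prop = logp1
            tree.alpha = min(1.0, float(np.exp(min(0.0, joint - joint0))))
            tree.n_alpha = 1
            return tree
        t1 = build_tree(theta, r, grad, logu, v, j - 1, eps, joint0)
        tree = t1
        if t1.keep_going:
            if v == -1:
                t2 = build_tree(t1.theta_minus, t1.r_minus, t1.grad_minus, logu, v, j - 1, eps, joint0)
                t1.theta_minus, t1.r_minus, t1.grad_minus = (
                    t2.theta_minus, t2.r_minus, t2.grad_minus,
                )
            else:
                t2 = build_tree(t1.theta_plus, t1.r_plus, t1.grad_plus, logu, v, j - 1, eps, joint0)
                t1.theta_plus, t1.r_plus, t1.grad_plus = (
                    t2.theta_plus, t2.r_plus, t2.grad_plus,
                )
            total = t1.n_valid + t2.n_valid
            if total > 0 and rng.uniform() < t2.n_valid / total:
                t1.theta_prop = t2.theta_prop
                t1.grad_prop = t2.grad_prop
                t1.logp_prop = t2.logp_prop
            dtheta = t1.theta_plus - t1.theta_minus
            no_uturn = (
                float(dtheta @ (inv_mass * t1.r_minus)) >= 0
                and float(dtheta @ (inv_mass * t1.r_plus)) >= 0
            )
            t1.keep_going = t2.keep_going and no_uturn
            t1.n_valid = total
            t1.alpha += t2.alpha
            t1.n_alpha += t2.n_alpha
            t1.divergent = t1.divergent or t2.divergent
        return tree

    total_iters = n_warmup + n_samples
    for it in range(total_iters):
        r0 = rng.standard_normal(dim) * mass_sd
        joint0 = _hamiltonian(logp, r0, inv_mass)
        logu = joint0 + np.log(rng.uniform())
        theta_minus = theta_plus = theta
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        theta_new, grad_new, logp_new = theta, grad, logp
        j, n_valid, keep_going = 0, 1, True
        alpha_sum, n_alpha, divergent = 0.0, 1, False
        while keep_going and j < max_depth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                tree = build_tree(theta_minus, r_minus, grad_minus, logu, v, j, eps, joint0)
                theta_minus, r_minus, grad_minus = (
                    tree.theta_minus, tree.r_minus, tree.grad_minus,
                )
            else:
                tree = build_tree(theta_plus, r_plus, grad_plus, logu, v, j, eps, joint0)
                theta_plus, r_plus, grad_plus = (
                    tree.theta_plus, tree.r_plus, tree.grad_plus,
                )
            if tree.keep_going and tree.n_valid > 0:
                if rng.uniform() < tree.n_valid / max(n_valid, 1):
                    theta_new, grad_new, logp_new = (
                        tree.theta_prop, tree.grad_prop, tree.logp_prop,
                    )
            n_valid += tree.n_valid
            alpha_sum, n_alpha = alpha_sum + tree.alpha, n_alpha + tree.n_alpha
            divergent = divergent or tree.divergent
            dtheta = theta_plus - theta_minus
            keep_going = (
                tree.keep_going
                and float(dtheta @ (inv_mass * r_minus)) >= 0
                and float(dtheta @ (inv_mass * r_plus)) >= 0
            )
            j += 1
        theta, grad, logp = theta_new, grad_new, logp_new
        if divergent and it >= n_warmup:
            n_divergent += 1
        if it < n_warmup:
            frac = 1.0 / (it + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha_sum / n_alpha)
            log_eps = mu - np.sqrt(it + 1) / gamma_da * h_bar
            w = (it + 1) ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            samples[it - n_warmup] = theta

    return samples, {"n_divergent": n_divergent, "step_size": eps}
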