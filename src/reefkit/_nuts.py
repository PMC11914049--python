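"""A compact No-U-Turn sampler with dual-averaging step-size adaptation.

Implements the classic recursive tree-doubling NUTS (slice variant) on an
unconstrained parameter vector, with a diagonal mass matrix estimated during
the tuning phase.  Models supply ``logp_and_grad(z) -> (float, ndarray)``;
bounded or positive parameters are expected to be transformed to the real
line by the caller (with the log-Jacobian included in ``logp``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_sample", "NutsResult"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim), post-tuning
    step_size: float
    mass_diag: np.ndarray
    n_divergent: int
    mean_accept: float


def _leapfrog(logp_and_grad, z, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    z = z + eps * inv_mass * r
    logp, grad = logp_and_grad(z)
    r = r + 0.5 * eps * grad
    return z, r, logp, grad


def _joint(logp, r, inv_mass):
    return logp - 0.5 * float(np.sum(inv_mass * r * r))


def _find_reasonable_epsilon(logp_and_grad, z0, rng, inv_mass):
    eps = 1.0
    logp0, grad0 = logp_and_grad(z0)
    r0 = rng.standard_normal(z0.size) / np.sqrt(inv_mass)
    joint0 = _joint(logp0, r0, inv_mass)
    z, r, logp, _ = _leapfrog(logp_and_grad, z0, r0, grad0, eps, inv_mass)
    log_ratio = _joint(logp, r, inv_mass) - joint0
    if not np.isfinite(log_ratio):
        log_ratio = -np.inf
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        z, r, logp, _ = _leapfrog(logp_and_grad, z0, r0, grad0, eps, inv_mass)
        log_ratio = _joint(logp, r, inv_mass) - joint0
        if not np.isfinite(log_ratio):
            log_ratio = -np.inf
        if direction * log_ratio <= direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_and_grad, z, r, grad, logu, v, depth, eps, joint0, inv_mass, rng):
    """Recursive doubling; returns the standard NUTS tuple."""
    if depth == 0:
        z1, r1, logp1, grad1 = _leapfrog(logp_and_grad, z, r, grad, v * eps, inv_mass)
        joint = _joint(logp1, r1, inv_mass)
        if not np.isfinite(joint):
            joint = -np.inf
        n1 = int(logu <= joint)
        s1 = int(logu < joint + _DELTA_MAX)
        accept = min(1.0, np.exp(min(joint - joint0, 0.0)))
        return z1, r1, grad1, z1, r1, grad1, z1, logp1, grad1, n1, s1, accept, 1
    # first subtree
    (zm, rm, gm, zp, rp, gp, z1, logp1, grad1, n1, s1, a1, na1) = _build_tree(
        logp_and_grad, z, r, grad, logu, v, depth - 1, eps, joint0, inv_mass, rng
    )
    if s1 == 1:
        if v == -1:
            (zm, rm, gm, _, _, _, z2, logp2, grad2, n2, s2, a2, na2) = _build_tree(
                logp_and_grad, zm, rm, gm, logu, v, depth - 1, eps, joint0, inv_mass, rng
            )
        else:
            (_, _, _, zp, rp, gp, z2, logp2, grad2, n2, s2, a2, na2) = _build_tree(
                logp_and_grad, zp, rp, gp, logu, v, depth - 1, eps, joint0, inv_mass, rng
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            z1, logp1, grad1 = z2, logp2, grad2
        a1 += a2
        na1 += na2
        dz = zp - zm
        s1 = s2 * int(np.dot(dz, inv_mass * rm) >= 0) * int(np.dot(dz, inv_mass * rp) >= 0)
        n1 += n2
    return zm, rm, gm, zp, rp, gp, z1, logp1, grad1, n1, s1, a1, na1


def nuts_sample(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    z0: np.ndarray,
    n_tune: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; the first ``n_tune`` iterations are discarded."""
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    mass_diag = np.ones(dim)          # momentum covariance
    inv_mass = 1.0 / mass_diag
    eps = _find_reasonable_epsilon(logp_and_grad, z, rng, inv_mass)

    # dual-averaging state (Hoffman & Gelman 2014, defaults)
    mu = np.log(10.0 * eps)
    eps_bar, h_bar = 1.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    logp, grad = logp_and_grad(z)
    draws = np.empty((n_draws, dim))
    window = []                        # tuning draws for mass estimation
    mass_switch = int(n_tune * 0.6) if n_tune >= 100 else n_tune + 1
    n_divergent = 0
    accept_sum = 0.0
    n_total = n_tune + n_draws

    for it in range(n_total):
        r0 = rng.standard_normal(dim) * np.sqrt(mass_diag)
        joint0 = _joint(logp, r0, inv_mass)
        logu = joint0 + np.log(rng.random())
        zm = zp = z
        rm = rp = r0
        gm = gp = grad
        depth, n_kept, s = 0, 1, 1
        alpha, n_alpha = 1.0, 1
        while s == 1 and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (zm, rm, gm, _, _, _, z1, logp1, grad1, n1, s1, alpha, n_alpha) = _build_tree(
                    logp_and_grad, zm, rm, gm, logu, v, depth, eps, joint0, inv_mass, rng
                )
            else:
                (_, _, _, zp, rp, gp, z1, logp1, grad1, n1, s1, alpha, n_alpha) = _build_tree(
                    logp_and_grad, zp, rp, gp, logu, v, depth, eps, joint0, inv_mass, rng
                )
            if s1 == 1 and n1 > 0 and rng.random() < min(1.0, n1 / n_kept):
                z, logp, grad = z1, logp1, grad1
            n_kept += n1
            dz = zp - zm
            s = s1 * int(np.dot(dz, inv_mass * rm) >= 0) * int(np.dot(dz, inv_mass * rp) >= 0)
            depth += 1
        if s1 == 0 and not np.isfinite(logp1):
            n_divergent += 1

        accept_prob = alpha / max(n_alpha, 1)
        if it < n_tune:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            eps_bar = float(np.exp(eta * log_eps + (1 - eta) * np.log(eps_bar)))
            eps = float(np.exp(log_eps))
            if it >= mass_switch // 3:
                window.append(z.copy())
            if it == mass_switch and len(window) > 10:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                mass_diag = 1.0 / np.clip(var, 1e-8, None)
                inv_mass = 1.0 / mass_diag
                eps = _find_reasonable_epsilon(logp_and_grad, z, rng, inv_mass)
                mu = np.log(10.0 * eps)
                eps_bar, h_bar, adapt_count = 1.0, 0.0, 0
                window = []
        else:
            if it == n_tune:
                eps = eps_bar
            accept_sum += accept_prob
            draws[it - n_tune] = z

    return NutsResult(
        draws=draws,
        step_size=eps,
        mass_diag=mass_diag,
        n_divergent=n_divergent,
        mean_accept=accept_sum / max(n_draws, 1),
    )
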