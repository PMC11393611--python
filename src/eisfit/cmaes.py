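"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda) CMA-ES with
cumulative step-size adaptation and rank-one / rank-mu covariance updates,
for the low-dimensional (d = 7) bounded maximum-likelihood fits used here.
Minimizes an unconstrained objective; box constraints are handled upstream
by a sigmoidal reparameterization so every proposal is feasible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CMAResult", "minimize_cmaes"]


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    n_generations: int
    converged: bool


def minimize_cmaes(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    seed: int | np.random.SeedSequence,
    max_evals: int = 20_000,
    popsize: int | None = None,
    f_tol: float = 1e-8,
    stagnation_generations: int = 50,
) -> CMAResult:
    """Minimize ``objective`` starting from ``x0`` with initial step ``sigma0``.

    Deterministic for a fixed seed.  Converged means the best objective value
    improved by less than ``f_tol`` over ``stagnation_generations``
    consecutive generations before the evaluation budget ran out.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(x0, dtype=float).copy()
    d = mean.size
    sigma = float(sigma0)

    lam = popsize if popsize is not None else 4 + int(3 * np.log(d))
    mu = lam // 2
    raw_weights = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    weights = raw_weights / raw_weights.sum()
    mu_eff = 1.0 / np.sum(weights**2)

    # Strategy constants (Hansen's standard defaults).
    c_sigma = (mu_eff + 2.0) / (d + mu_eff + 5.0)
    d_sigma = 1.0 + 2.0 * max(0.0, np.sqrt((mu_eff - 1.0) / (d + 1.0)) - 1.0) + c_sigma
    c_c = (4.0 + mu_eff / d) / (d + 4.0 + 2.0 * mu_eff / d)
    c_1 = 2.0 / ((d + 1.3) ** 2 + mu_eff)
    c_mu = min(1.0 - c_1, 2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((d + 2.0) ** 2 + mu_eff))
    chi_d = np.sqrt(d) * (1.0 - 1.0 / (4.0 * d) + 1.0 / (21.0 * d**2))

    C = np.eye(d)
    p_sigma = np.zeros(d)
    p_c = np.zeros(d)

    best_x = mean.copy()
    best_f = float(objective(mean))
    n_evals = 1
    gen = 0
    stagnant = 0
    prev_best = best_f
    converged = False

    while n_evals + lam <= max_evals:
        gen += 1
        # Eigendecomposition of C for sampling (cheap at d = 7).
        C = (C + C.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-30)
        D = np.sqrt(eigvals)
        inv_sqrt_C = eigvecs @ np.diag(1.0 / D) @ eigvecs.T

        z = rng.standard_normal((lam, d))
        y = z @ (eigvecs * D).T  # y_k = B D z_k
        x = mean + sigma * y
        f = np.array([objective(xi) for xi in x])
        n_evals += lam

        order = np.argsort(f)
        if f[order[0]] < best_f:
            best_f = float(f[order[0]])
            best_x = x[order[0]].copy()

        y_sel = y[order[:mu]]
        y_w = weights @ y_sel
        mean = mean + sigma * y_w

        p_sigma = (1.0 - c_sigma) * p_sigma + np.sqrt(
            c_sigma * (2.0 - c_sigma) * mu_eff
        ) * (inv_sqrt_C @ y_w)
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / np.sqrt(1.0 - (1.0 - c_sigma) ** (2.0 * gen))
            < (1.4 + 2.0 / (d + 1.0)) * chi_d
        )
        p_c = (1.0 - c_c) * p_c + h_sigma * np.sqrt(c_c * (2.0 - c_c) * mu_eff) * y_w

        rank_mu = (y_sel * weights[:, None]).T @ y_sel
        C = (
            (1.0 - c_1 - c_mu) * C
            + c_1 * (np.outer(p_c, p_c) + (1.0 - h_sigma) * c_c * (2.0 - c_c) * C)
            + c_mu * rank_mu
        )
        sigma *= np.exp((c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_d - 1.0))
        sigma = min(sigma, 1e8)

        if prev_best - best_f < f_tol:
            stagnant += 1
        else:
            stagnant = 0
        prev_best = best_f
        if stagnant >= stagnation_generations:
            converged = True
            break
        if sigma < 1e-12:
            converged = True
            break

    return CMAResult(best_x, best_f, n_evals, gen, converged)
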