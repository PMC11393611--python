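"""Adaptive-covariance MCMC over the circuit parameters, with diagnostics.

Sampling uses a Haario-style adaptive Metropolis walk: the Gaussian
proposal covariance is adapted toward the (scaled) empirical covariance of
the chain history, and a global step-size factor is tuned toward the
optimal ~0.234 acceptance rate.  The prior is uniform over the CMA-ES
boundaries in natural parameter space; sampling runs in the same
log10-transformed coordinates as fitting, with the Jacobian applied so the
natural-space prior stays uniform.

Also provides split-chain Gelman-Rubin diagnostics, posterior summaries
(histograms, credible intervals, pairwise correlations), a posterior
overlap metric used to declare charge-transfer resistances at two analyte
concentrations distinct, and the electrode amalgamation quality control
used before pooling titration data across electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .circuit import PARAM_NAMES, CircuitParameters, ImpedanceSpectrum
from .likelihood import (
    LOG_SCALE_MASK,
    BoxTransform,
    FitResult,
    ParameterBounds,
    log_likelihood,
)

__all__ = [
    "PosteriorSamples",
    "ConvergenceReport",
    "adaptive_metropolis",
    "run_mcmc",
    "gelman_rubin",
    "posterior_summary",
    "rct_separation",
    "electrode_amalgamation_qc",
]

LN10 = np.log(10.0)


@dataclass
class PosteriorSamples:
    """Per-chain MCMC draws in natural parameter space.

    ``chains`` has shape ``(n_chains, n_iterations, n_params)``.  ``pooled``
    concatenates the post-burn-in tail of every chain.
    """

    chains: np.ndarray
    burn_in: int
    seed: int
    param_names: tuple[str, ...] = PARAM_NAMES
    acceptance_rates: np.ndarray | None = None
    stuck_chains: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.chains = np.asarray(self.chains, dtype=float)
        if self.chains.ndim != 3:
            raise ValueError("chains must have shape (n_chains, n_iter, n_params)")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.chains.shape[1]

    @property
    def retained(self) -> np.ndarray:
        """Post-burn-in draws, shape (n_chains, n_iter - burn_in, n_params)."""
        return self.chains[:, self.burn_in :, :]

    @property
    def pooled(self) -> np.ndarray:
        """All retained draws pooled across chains, shape (M, n_params)."""
        r = self.retained
        return r.reshape(-1, r.shape[-1])

    def parameter(self, name: str) -> np.ndarray:
        """Pooled draws of one named parameter."""
        return self.pooled[:, self.param_names.index(name)]


@dataclass(frozen=True)
class ConvergenceReport:
    psrf: np.ndarray
    ess: np.ndarray
    passed: bool
    threshold: float
    param_names: tuple[str, ...] = PARAM_NAMES


def adaptive_metropolis(
    log_target: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    seed: int | np.random.SeedSequence,
    initial_cov: np.ndarray | None = None,
    adapt_start: int = 100,
    target_acceptance: float = 0.234,
) -> tuple[np.ndarray, float]:
    """One adaptive-covariance Metropolis chain targeting ``log_target``.

    Adaptation begins after ``adapt_start`` iterations: the proposal
    covariance tracks the empirical covariance of the visited states with a
    decaying learning rate, and a global log-scale factor is nudged toward
    the target acceptance rate.  Returns ``(chain, acceptance_rate)`` where
    ``chain`` has shape ``(n_iter, d)`` (the initial point is not stored).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    fx = float(log_target(x))
    if not np.isfinite(fx):
        raise ValueError("initial point has non-finite target density")

    cov = (
        np.asarray(initial_cov, dtype=float).copy()
        if initial_cov is not None
        else np.eye(d)
    )
    mean = x.copy()
    log_lambda = 0.0
    jitter = 1e-12 * np.eye(d)
    chol = np.linalg.cholesky(cov + jitter)

    chain = np.empty((n_iter, d))
    n_accept = 0
    for i in range(n_iter):
        step = np.exp(0.5 * log_lambda) * (chol @ rng.standard_normal(d))
        proposal = x + step
        fp = float(log_target(proposal))
        accepted = np.log(rng.uniform()) < fp - fx
        if accepted:
            x, fx = proposal, fp
            n_accept += 1
        chain[i] = x

        if i >= adapt_start:
            t = i - adapt_start + 1.0
            # Equal-weight running covariance of the full post-adaptation
            # history (Haario); the global scale is tuned separately toward
            # the target acceptance rate with a decaying learning rate.
            delta = x - mean
            mean = mean + delta / (t + 1.0)
            cov = cov + (np.outer(delta, delta) * t / (t + 1.0) - cov) / (t + 1.0)
            log_lambda += t**-0.6 * (float(accepted) - target_acceptance)
            try:
                chol = np.linalg.cholesky(cov + jitter)
            except np.linalg.LinAlgError:
                cov = cov + 1e-9 * np.eye(d)
                chol = np.linalg.cholesky(cov)

    return chain, n_accept / n_iter


def run_mcmc(
    spectrum: ImpedanceSpectrum,
    bounds: ParameterBounds | None = None,
    init: CircuitParameters | None = None,
    n_chains: int = 3,
    n_iter: int = 10_000,
    burn_in: int = 3_000,
    seed: int = 0,
) -> PosteriorSamples:
    """Sample the posterior of the circuit parameters for one spectrum.

    The target density is the polar Gaussian log-likelihood plus a prior
    uniform over ``bounds`` in natural space (-inf outside).  Chains are
    initialised from ``init`` (typically the CMA-ES maximum-likelihood
    point).  Deterministic for a fixed seed.  A chain whose post-adaptation
    acceptance collapses to zero is flagged in ``stuck_chains``, not raised.
    """
    if bounds is None:
        bounds = ParameterBounds.default()
    if init is None:
        raise ValueError("init is required (use the CMA-ES best fit)")
    if not bounds.contains(init):
        raise ValueError("initial point lies outside the prior bounds")
    if not (0 <= burn_in < n_iter):
        raise ValueError("burn_in must be smaller than n_iter")

    transform = BoxTransform(bounds)
    t_lower, t_upper = transform.t_lower, transform.t_upper

    def log_posterior_transformed(theta: np.ndarray) -> float:
        if np.any(theta < t_lower) or np.any(theta > t_upper):
            return -np.inf
        natural = transform.to_natural(theta)
        # Jacobian of theta -> natural for log10 coordinates keeps the
        # natural-space prior uniform: dx/dtheta = ln(10) * x = ln(10) * 10^theta.
        log_jac = LN10 * np.sum(theta[LOG_SCALE_MASK])
        return log_likelihood(spectrum, CircuitParameters.from_array(natural)) + log_jac

    theta0 = transform.to_transformed(init.as_array())
    width = t_upper - t_lower
    initial_cov = np.diag((1e-3 * width) ** 2)

    chains = np.empty((n_chains, n_iter, len(PARAM_NAMES)))
    rates = np.empty(n_chains)
    stuck: list[int] = []
    for c, child in enumerate(np.random.SeedSequence(seed).spawn(n_chains)):
        chain_t, rate = adaptive_metropolis(
            log_posterior_transformed, theta0, n_iter, child, initial_cov=initial_cov
        )
        rates[c] = rate
        if rate == 0.0:
            stuck.append(c)
        natural = chain_t.copy()
        natural[:, LOG_SCALE_MASK] = 10.0 ** natural[:, LOG_SCALE_MASK]
        chains[c] = natural

    return PosteriorSamples(
        chains=chains,
        burn_in=burn_in,
        seed=seed,
        acceptance_rates=rates,
        stuck_chains=tuple(stuck),
    )


def _split_chains(retained: np.ndarray) -> np.ndarray:
    """Split each chain in half, doubling the chain count (split-R-hat)."""
    m, n, d = retained.shape
    half = n // 2
    return np.concatenate([retained[:, :half, :], retained[:, half : 2 * half, :]], axis=0)


def _ess_one(sequences: np.ndarray) -> float:
    """Effective sample size of one parameter from (m, n) sequences.

    Uses chain-averaged autocorrelations with Geyer's initial positive
    sequence truncation.
    """
    m, n = sequences.shape
    centred = sequences - sequences.mean(axis=1, keepdims=True)
    var = centred.var(axis=1).mean()
    if var == 0:
        return float(m * n)
    # FFT autocovariance per chain, averaged.
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centred, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    rho = acov.mean(axis=0) / var
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / max(tau, 1.0))


def gelman_rubin(samples: PosteriorSamples, threshold: float = 1.05) -> ConvergenceReport:
    """Split-chain potential scale reduction factor (R-hat) per parameter.

    For m split half-chains of length n with per-chain means x̄_j and
    variances s²_j:  W = mean(s²_j), B/n = var(x̄_j),
    R̂ = sqrt(((n-1)/n · W + B/n) / W).  Passes when every parameter's R̂ is
    below ``threshold``.
    """
    if samples.n_chains < 2:
        raise ValueError("at least 2 chains are required for the diagnostic")
    retained = samples.retained
    if retained.shape[1] < 10:
        raise ValueError("at least 10 retained draws per chain are required")

    split = _split_chains(retained)  # (2m, n//2, d)
    m, n, d = split.shape
    chain_means = split.mean(axis=1)  # (2m, d)
    chain_vars = split.var(axis=1, ddof=1)  # (2m, d)
    w = chain_vars.mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(((n - 1) / n * w + b_over_n) / w)
    psrf = np.where(w == 0, 1.0, psrf)

    ess = np.array([_ess_one(split[:, :, k]) for k in range(d)])
    return ConvergenceReport(
        psrf=psrf,
        ess=ess,
        passed=bool(np.all(psrf < threshold)),
        threshold=threshold,
        param_names=samples.param_names,
    )


def posterior_summary(
    samples: PosteriorSamples, bins: int = 40, interval: float = 0.95
) -> dict:
    """Histograms, central credible intervals and the pairwise correlation matrix.

    Returns a dict with per-parameter ``histograms`` (counts, bin edges),
    ``medians``, ``intervals`` (lower, upper central ``interval`` bounds)
    and the full ``correlation`` matrix (symmetric, unit diagonal).
    """
    pooled = samples.pooled
    if pooled.shape[0] == 0:
        raise ValueError("empty pooled sample")
    d = pooled.shape[1]
    lo_q = 100.0 * (1.0 - interval) / 2.0
    hi_q = 100.0 - lo_q

    histograms = {}
    medians = {}
    intervals = {}
    for k, name in enumerate(samples.param_names):
        col = pooled[:, k]
        counts, edges = np.histogram(col, bins=bins)
        histograms[name] = (counts, edges)
        medians[name] = float(np.median(col))
        intervals[name] = (float(np.percentile(col, lo_q)), float(np.percentile(col, hi_q)))

    if pooled.shape[0] == 1:
        corr = np.eye(d)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(pooled, rowvar=False)
        corr = np.where(np.isnan(corr), 0.0, corr)
        np.fill_diagonal(corr, 1.0)
    return {
        "histograms": histograms,
        "medians": medians,
        "intervals": intervals,
        "correlation": corr,
        "param_names": samples.param_names,
    }


def rct_separation(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    parameter: str = "R_ct",
    interval: float = 0.99,
    threshold: float = 0.01,
) -> tuple[float, bool]:
    """Posterior overlap between two fits' marginals for one parameter.

    The overlap is the fraction of each posterior's pooled draws falling
    inside the central ``interval`` credible interval of the other,
    symmetrized by averaging.  Distinct when overlap < ``threshold`` —
    operationalizing the visual "the distributions show no overlap" check
    used to validate titration steps.
    """
    a = samples_a.parameter(parameter)
    b = samples_b.parameter(parameter)
    if a.size == 0 or b.size == 0:
        raise ValueError("both posteriors must be non-empty")
    lo_q = 100.0 * (1.0 - interval) / 2.0
    hi_q = 100.0 - lo_q
    a_lo, a_hi = np.percentile(a, [lo_q, hi_q])
    b_lo, b_hi = np.percentile(b, [lo_q, hi_q])
    frac_a_in_b = np.mean((a >= b_lo) & (a <= b_hi))
    frac_b_in_a = np.mean((b >= a_lo) & (b <= a_hi))
    overlap = float((frac_a_in_b + frac_b_in_a) / 2.0)
    return overlap, overlap < threshold


def electrode_amalgamation_qc(
    protein_free_fits: Sequence, tolerance: float = 0.35
) -> list[int]:
    """Select electrodes whose protein-free R_ct values are similar enough to pool.

    Accepts a sequence of :class:`~eisfit.likelihood.FitResult` (or bare
    R_ct values in Ω) and returns the indices of the largest subset whose
    values all lie within ``±tolerance`` (relative) of the subset median.
    Ties go to the subset with the smallest relative spread.  The default
    35% tolerance pools protein-free electrodes at 7.7, 10.4 and 12.9 kΩ
    (subset median 10.4 kΩ).
    """
    if len(protein_free_fits) == 0:
        raise ValueError("no electrodes supplied")
    if len(protein_free_fits) < 2:
        raise ValueError("at least 2 electrodes are required for pooling QC")

    def rct_of(item) -> float:
        if isinstance(item, FitResult):
            return item.best_fit.R_ct
        if isinstance(item, CircuitParameters):
            return item.R_ct
        return float(item)

    values = np.array([rct_of(f) for f in protein_free_fits])
    order = np.argsort(values)
    sorted_vals = values[order]
    n = len(values)

    best: tuple[int, float] | None = None  # (size, -spread) maximized
    best_window: tuple[int, int] | None = None
    for i in range(n):
        for j in range(i, n):  # the optimal subset is contiguous in sorted order
            window = sorted_vals[i : j + 1]
            med = float(np.median(window))
            if window[0] >= med * (1.0 - tolerance) and window[-1] <= med * (1.0 + tolerance):
                spread = (window[-1] - window[0]) / med
                key = (j - i + 1, -spread)
                if best is None or key > best:
                    best = key
                    best_window = (i, j)

    i, j = best_window
    return sorted(int(order[k]) for k in range(i, j + 1))
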