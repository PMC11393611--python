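"""Gaussian log-likelihood in Bode (polar) form and CMA-ES maximum likelihood.

The error model assumes independent, identically distributed Gaussian noise
on the impedance phase (SD ``sigma1``, radians) and magnitude (SD ``sigma2``,
Ω).  Fitting is performed on the polar form of the data: complex-plane
residuals would over-weight the very large low-frequency impedances.

Scale parameters (R_s, R_ct, Z_w, Q, sigma2) span orders of magnitude and
are optimized in log10 space; alpha and sigma1 in natural space.  The
optimizer works in an unbounded coordinate mapped through a logistic
sigmoid into the (transformed) box, so every proposal is feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from .circuit import (
    PARAM_NAMES,
    CircuitParameters,
    ImpedanceSpectrum,
    randles_impedance,
    to_polar,
)
from .cmaes import minimize_cmaes

__all__ = ["ParameterBounds", "FitResult", "BoxTransform", "log_likelihood", "fit_cmaes"]

#: Indices of parameters handled in log10 space (all "scale" parameters).
LOG_SCALE_INDEX = np.array([0, 1, 2, 3, 6])  # R_s, R_ct, Z_w, Q, sigma2
LOG_SCALE_MASK = np.zeros(len(PARAM_NAMES), dtype=bool)
LOG_SCALE_MASK[LOG_SCALE_INDEX] = True

#: Wide default boundaries; overridable via config files.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "R_s": (0.1, 1e5),
    "R_ct": (1.0, 1e7),
    "Z_w": (1.0, 1e6),
    "Q": (1e-9, 1e-3),
    "alpha": (0.4, 1.0),
    "sigma1": (1e-5, 1.0),
    "sigma2": (1e-2, 1e5),
}


@dataclass(frozen=True)
class ParameterBounds:
    """Hard box boundaries for the seven model parameters."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != (len(PARAM_NAMES),) or upper.shape != (len(PARAM_NAMES),):
            raise ValueError("bounds must be 7-vectors in canonical parameter order")
        if np.any(lower <= 0):
            raise ValueError("lower bounds must be strictly positive")
        if np.any(lower >= upper):
            raise ValueError("each lower bound must be below its upper bound")
        if upper[4] > 1.0:
            raise ValueError("alpha upper bound cannot exceed 1")

    @classmethod
    def default(cls) -> "ParameterBounds":
        lower = np.array([DEFAULT_BOUNDS[n][0] for n in PARAM_NAMES])
        upper = np.array([DEFAULT_BOUNDS[n][1] for n in PARAM_NAMES])
        return cls(lower, upper)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[float, float]]) -> "ParameterBounds":
        """Build bounds from ``{name: (lower, upper)}``, defaulting missing names."""
        merged = dict(DEFAULT_BOUNDS)
        for name, pair in mapping.items():
            if name not in merged:
                raise KeyError(f"unknown parameter {name!r}")
            merged[name] = (float(pair[0]), float(pair[1]))
        lower = np.array([merged[n][0] for n in PARAM_NAMES])
        upper = np.array([merged[n][1] for n in PARAM_NAMES])
        return cls(lower, upper)

    def contains(self, params: CircuitParameters | np.ndarray) -> bool:
        vec = params.as_array() if isinstance(params, CircuitParameters) else np.asarray(params)
        return bool(np.all(vec >= self.lower) and np.all(vec <= self.upper))

    def as_mapping(self) -> dict[str, tuple[float, float]]:
        return {n: (float(lo), float(hi)) for n, lo, hi in zip(PARAM_NAMES, self.lower, self.upper)}


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit output."""

    best_fit: CircuitParameters
    log_likelihood_value: float
    n_evaluations: int
    seed: int
    converged: bool


class BoxTransform:
    """Coordinate transforms between natural, log10-box and unbounded spaces.

    * natural space: the seven parameters in their physical units;
    * transformed space: log10 applied to the scale parameters, so the box
      becomes well-conditioned;
    * unbounded space: logistic-sigmoid image of the transformed box, used
      by CMA-ES so proposals are always feasible.
    """

    def __init__(self, bounds: ParameterBounds):
        self.bounds = bounds
        self.t_lower = self._to_transformed(bounds.lower)
        self.t_upper = self._to_transformed(bounds.upper)
        self.t_width = self.t_upper - self.t_lower

    @staticmethod
    def _to_transformed(natural: np.ndarray) -> np.ndarray:
        out = np.asarray(natural, dtype=float).copy()
        out[LOG_SCALE_MASK] = np.log10(out[LOG_SCALE_MASK])
        return out

    @staticmethod
    def _to_natural(transformed: np.ndarray) -> np.ndarray:
        out = np.asarray(transformed, dtype=float).copy()
        out[LOG_SCALE_MASK] = 10.0 ** out[LOG_SCALE_MASK]
        return out

    to_transformed = staticmethod(_to_transformed)
    to_natural = staticmethod(_to_natural)

    def unbounded_to_natural(self, x: np.ndarray) -> np.ndarray:
        u = expit(np.asarray(x, dtype=float))
        return self._to_natural(self.t_lower + self.t_width * u)

    def natural_to_unbounded(self, natural: np.ndarray) -> np.ndarray:
        t = self._to_transformed(np.asarray(natural, dtype=float))
        u = (t - self.t_lower) / self.t_width
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        return np.log(u / (1.0 - u))

    def clip_transformed(self, t: np.ndarray) -> np.ndarray:
        return np.clip(t, self.t_lower, self.t_upper)


def log_likelihood(spectrum: ImpedanceSpectrum, params: CircuitParameters) -> float:
    """iid Gaussian log-likelihood of the spectrum in polar (Bode) form.

    With model polar values (|Z|_m, φ_m) at each of the N frequencies and
    observations (|Z|_o, φ_o)::

        L = -N ln(2π) - N ln σ1 - N ln σ2
            - Σ (φ_o - φ_m)² / (2 σ1²) - Σ (|Z|_o - |Z|_m)² / (2 σ2²)
    """
    if len(spectrum) == 0:
        raise ValueError("spectrum is empty")
    if params.sigma1 <= 0 or params.sigma2 <= 0:
        raise ValueError("noise standard deviations must be > 0")
    n = len(spectrum)
    z_model = randles_impedance(params, 2.0 * np.pi * spectrum.frequencies)
    mod_m = np.abs(z_model)
    phase_m = np.angle(z_model)
    mod_o, phase_o = to_polar(spectrum)
    return float(
        -n * np.log(2.0 * np.pi)
        - n * np.log(params.sigma1)
        - n * np.log(params.sigma2)
        - np.sum((phase_o - phase_m) ** 2) / (2.0 * params.sigma1**2)
        - np.sum((mod_o - mod_m) ** 2) / (2.0 * params.sigma2**2)
    )


def fit_cmaes(
    spectrum: ImpedanceSpectrum,
    bounds: ParameterBounds | None = None,
    seed: int = 0,
    max_evals: int = 20_000,
) -> FitResult:
    """Maximum-likelihood fit of the modified Randles circuit via CMA-ES.

    Deterministic for a fixed seed.  Spectra with fewer than 7 points are
    rejected (the model has seven parameters).  Because the likelihood
    surface has occasional local optima, independent starts are run until
    the two best objective values agree (the same basin was found twice),
    up to four starts, and the best kept.  A result where no start met the
    stagnation tolerance is flagged unconverged, not raised.
    """
    if len(spectrum) < 7:
        raise ValueError(
            f"spectrum has {len(spectrum)} points; at least 7 are required to "
            "identify the 7-parameter model"
        )
    if bounds is None:
        bounds = ParameterBounds.default()
    transform = BoxTransform(bounds)

    def negative_ll(x_unbounded: np.ndarray) -> float:
        params = CircuitParameters.from_array(transform.unbounded_to_natural(x_unbounded))
        value = log_likelihood(spectrum, params)
        return -value if np.isfinite(value) else 1e300

    seed_seq = np.random.SeedSequence(seed)
    x0 = np.zeros(len(PARAM_NAMES))  # box centre in transformed space
    total_evals = 0
    results = []
    converged = False
    for attempt, child in enumerate(seed_seq.spawn(4)):
        result = minimize_cmaes(
            negative_ll, x0, sigma0=0.5, seed=child, max_evals=max_evals
        )
        total_evals += result.n_evaluations
        results.append(result)
        converged = converged or result.converged
        values = sorted(r.fun for r in results)
        if attempt >= 1 and converged and values[1] - values[0] < 0.1:
            break
    best = min(results, key=lambda r: r.fun)

    best_params = CircuitParameters.from_array(transform.unbounded_to_natural(best.x))
    return FitResult(
        best_fit=best_params,
        log_likelihood_value=log_likelihood(spectrum, best_params),
        n_evaluations=total_evals,
        seed=seed,
        converged=converged,
    )
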