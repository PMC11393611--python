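"""Synthetic-data generators emulating every input the pipeline consumes.

Each generator is a pure function of (truth, seed): identical inputs give
identical outputs.  Noise on spectra is applied in polar coordinates —
Gaussian perturbations of phase (σ1) and magnitude (σ2) — mirroring the
likelihood's error model, so estimator consistency holds by construction.

The default "fig5-like" scenario uses plausible test values for a
polymer-glycan-modified screen-printed gold electrode read out with a
ferricyanide redox probe; they are synthetic testing values, not measured
ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import TitrationSeries, Voltammogram
from .circuit import (
    CircuitParameters,
    ImpedanceSpectrum,
    log_frequency_grid,
    polar_to_cartesian,
    spectrum_from_model,
    to_polar,
)
from .cohort import RctCohort

__all__ = [
    "ScenarioConfig",
    "default_scenario",
    "generate_spectrum",
    "generate_titration",
    "generate_electrode_population",
    "generate_dcv",
]


@dataclass
class ScenarioConfig:
    """Ground-truth configuration for one simulated study.

    Collects the circuit truth (incl. the polar noise SDs σ1, σ2), the
    frequency sweep, the titration truth (Langmuir or Hill), the
    electrode-population spread, and the cyclic-voltammetry truth.
    """

    circuit: CircuitParameters
    f_min: float = 0.05
    f_max: float = 1.0e4
    points_per_decade: int = 10
    # Titration block
    titration_model: str = "langmuir"  # "langmuir" | "hill"
    k_binding: float = 6.3  # K_d or K_A, μg mL^-1
    hill_n: float = 5.7
    amplitude: float = 3.0
    concentrations: tuple[float, ...] = (15.0, 17.5, 20.0, 22.5, 25.0, 30.0)
    titration_noise: float = 0.0  # relative SD on R_ct,i
    # Electrode population block
    population_median_rct: float = 31.7e3  # Ω
    population_log_sd: float = 0.25  # SD of log10(R_ct)
    # DCV block
    dcv_peak_potential: float = 0.25  # V
    dcv_peak_width: float = 0.05  # Gaussian SD, V
    dcv_peak_charge: float = 0.35e-12 * 96485.0  # C; 0.35 pmol of 1-e transfers
    dcv_background: tuple[float, float, float, float] = (2e-7, 1e-6, -2e-6, 4e-6)
    dcv_scan_rate: float = 0.1  # V s^-1

    def __post_init__(self) -> None:
        if self.titration_model not in ("langmuir", "hill"):
            raise ValueError(f"unknown titration model {self.titration_model!r}")
        if self.k_binding <= 0 or self.hill_n <= 0:
            raise ValueError("binding truth parameters must be > 0")
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")

    def frequency_grid(self) -> np.ndarray:
        return log_frequency_grid(self.f_min, self.f_max, self.points_per_decade)

    def titration_response(self, concentrations: np.ndarray) -> np.ndarray:
        """Noiseless fractional R_ct response y(C) under the configured truth."""
        c = np.asarray(concentrations, dtype=float)
        if self.titration_model == "langmuir":
            return c / self.k_binding
        return (
            self.amplitude * c**self.hill_n / (self.k_binding**self.hill_n + c**self.hill_n)
        )


def default_scenario() -> ScenarioConfig:
    """Plausible galectin-titration-like test scenario (synthetic values)."""
    truth = CircuitParameters(
        R_s=200.0, R_ct=15e3, Z_w=3e3, Q=5e-7, alpha=0.9, sigma1=0.01, sigma2=150.0
    )
    return ScenarioConfig(circuit=truth)


def generate_spectrum(
    truth: CircuitParameters, frequencies, seed: int | np.random.SeedSequence = 0
) -> ImpedanceSpectrum:
    """Noisy spectrum: polar model values + N(0, σ1²) phase, N(0, σ2²) magnitude.

    A perturbation that would drive a magnitude non-positive is resampled
    (with a warning) rather than truncated, keeping the retained noise
    unbiased.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    clean = spectrum_from_model(truth, frequencies)
    mod, phase = to_polar(clean)
    noisy_phase = phase + rng.normal(0.0, truth.sigma1, size=phase.shape)
    noisy_mod = mod + rng.normal(0.0, truth.sigma2, size=mod.shape)
    bad = noisy_mod <= 0
    n_resampled = 0
    while np.any(bad):
        noisy_mod[bad] = mod[bad] + rng.normal(0.0, truth.sigma2, size=int(bad.sum()))
        n_resampled += int(bad.sum())
        bad = noisy_mod <= 0
    if n_resampled:
        warnings.warn(
            f"resampled {n_resampled} magnitude perturbation(s) that went non-positive",
            stacklevel=2,
        )
    z_real, z_imag = polar_to_cartesian(noisy_mod, noisy_phase)
    return ImpedanceSpectrum(clean.frequencies, z_real, z_imag)


def generate_titration(
    scenario: ScenarioConfig,
    rct_0: float,
    relative_noise: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> TitrationSeries:
    """Titration series R_ct,i = R_ct,0 (1 + y(C_i)) (1 + ε_i), ε ~ N(0, noise²)."""
    if rct_0 <= 0:
        raise ValueError("rct_0 must be > 0")
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    rng = np.random.default_rng(seed)
    c = np.asarray(scenario.concentrations, dtype=float)
    y = scenario.titration_response(c)
    eps = rng.normal(0.0, relative_noise, size=c.shape) if relative_noise > 0 else 0.0
    rct = rct_0 * (1.0 + y) * (1.0 + eps)
    return TitrationSeries(rct_0=rct_0, concentrations=c, rct=rct)


def generate_electrode_population(
    n: int,
    median_rct: float = 31.7e3,
    log_sd: float = 0.25,
    seed: int | np.random.SeedSequence = 0,
    label: str = "synthetic",
) -> RctCohort:
    """Log-normal electrode population: median ``median_rct``, log10-scale SD ``log_sd``.

    Positivity is guaranteed by construction; log_sd = 0 collapses to a
    constant cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if median_rct <= 0 or log_sd < 0:
        raise ValueError("median_rct must be > 0 and log_sd >= 0")
    rng = np.random.default_rng(seed)
    log10_vals = np.log10(median_rct) + rng.normal(0.0, log_sd, size=n)
    return RctCohort(label=label, values=10.0**log10_vals)


def generate_dcv(
    scenario: ScenarioConfig,
    potential_grid,
    seed: int | np.random.SeedSequence = 0,
    current_noise: float = 0.0,
) -> Voltammogram:
    """Voltammogram: cubic background + Gaussian faradaic peak + optional noise.

    The peak's time-integrated charge equals ``scenario.dcv_peak_charge``
    to quadrature accuracy: the current peak has potential-integrated area
    ``charge * scan_rate``.  The grid must cover the peak to ±5 widths.
    """
    e = np.asarray(potential_grid, dtype=float)
    e0, w = scenario.dcv_peak_potential, scenario.dcv_peak_width
    if e.min() > e0 - 5 * w or e.max() < e0 + 5 * w:
        raise ValueError("potential grid must cover the peak to +/- 5 peak widths")
    rng = np.random.default_rng(seed)
    background = np.polynomial.Polynomial(scenario.dcv_background)(e)
    area = scenario.dcv_peak_charge * scenario.dcv_scan_rate  # ∫ i dE
    peak = area / (w * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((e - e0) / w) ** 2)
    current = background + peak
    if current_noise > 0:
        current = current + rng.normal(0.0, current_noise, size=e.shape)
    return Voltammogram(potential=e, current=current, scan_rate=scenario.dcv_scan_rate)
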