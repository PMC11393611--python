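"""Binding-constant and surface-coverage analyses downstream of the EIS fits.

The impedimetric response variable throughout is the fractional change in
charge-transfer resistance, y_i = (R_ct,i - R_ct,0) / R_ct,0, measured at
analyte concentration C_i relative to the protein-free value R_ct,0.

* Langmuir analysis linearises y = C / K_d and regresses through the origin,
  so the gradient is 1/K_d.
* The Hill analysis fits y = A C^n / (K_A^n + C^n); n > 1 indicates
  cooperative (multivalent) binding and K_A is the concentration at half
  occupation.
* k_app converts a charge-transfer resistance into an apparent
  heterogeneous electron-transfer rate constant for the redox probe.
* ferrocene_coverage integrates the baseline-subtracted faradaic charge of
  a surface-confined voltammetric peak into a molar surface coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "Voltammogram",
    "langmuir_kd",
    "hill_fit",
    "k_app_from_rct",
    "mass_to_molar",
    "ferrocene_coverage",
    "GAS_CONSTANT",
    "FARADAY",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
FARADAY = 96485.0  # C mol^-1


@dataclass
class TitrationSeries:
    """Protein-free R_ct,0 plus (concentration, R_ct,i) titration points.

    Concentrations in μg mL⁻¹, resistances in Ω.  ``spread`` optionally
    carries per-point dispersion (Ω) for amalgamated multi-electrode sets.
    """

    rct_0: float
    concentrations: np.ndarray
    rct: np.ndarray
    spread: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rct = np.asarray(self.rct, dtype=float)
        if self.rct_0 <= 0:
            raise ValueError("rct_0 must be > 0")
        if self.concentrations.shape != self.rct.shape:
            raise ValueError("concentrations and rct must have the same length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.rct <= 0):
            raise ValueError("all rct values must be > 0")
        if self.spread is not None:
            self.spread = np.asarray(self.spread, dtype=float)
            if self.spread.shape != self.rct.shape:
                raise ValueError("spread must match the titration length")

    def __len__(self) -> int:
        return len(self.concentrations)

    @property
    def response(self) -> np.ndarray:
        """Fractional R_ct change y_i = (R_ct,i - R_ct,0) / R_ct,0."""
        return (self.rct - self.rct_0) / self.rct_0


@dataclass(frozen=True)
class BindingFit:
    """Result of a Langmuir or Hill binding fit."""

    model: str  # "langmuir" | "hill"
    k: float  # K_d (langmuir) or K_A (hill), μg mL^-1
    hill_n: float | None = None
    amplitude: float | None = None
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("langmuir", "hill"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.k <= 0:
            raise ValueError("binding constant must be > 0")
        if self.hill_n is not None and self.hill_n <= 0:
            raise ValueError("Hill coefficient must be > 0")


@dataclass
class Voltammogram:
    """Potential/current trace with its scan rate (V s⁻¹)."""

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.shape != self.current.shape:
            raise ValueError("potential and current must have the same length")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be > 0")


def langmuir_kd(series: TitrationSeries) -> BindingFit:
    """Langmuir dissociation constant from the linearised titration.

    Regresses y = (R_ct,i - R_ct,0)/R_ct,0 on C through the origin (zero
    intercept); the through-origin least-squares slope is Σ(C·y)/Σ(C²) and
    K_d = 1/slope.  Raises on a non-positive slope (no binding signal).
    """
    if len(series) < 2:
        raise ValueError("at least 2 titration points are required")
    c = series.concentrations
    y = series.response
    slope = float(np.sum(c * y) / np.sum(c * c))
    if slope <= 0:
        raise ValueError("non-positive regression slope: no binding signal")
    residuals = y - slope * c
    return BindingFit(model="langmuir", k=1.0 / slope, rss=float(np.sum(residuals**2)))


def _hill_curve(c: np.ndarray, amplitude: float, k_a: float, n: float) -> np.ndarray:
    return amplitude * c**n / (k_a**n + c**n)


def hill_fit(series: TitrationSeries) -> BindingFit:
    """Hill-equation fit y = A C^n / (K_A^n + C^n) by nonlinear least squares.

    At C = K_A the fitted response equals A/2 by construction.  Requires at
    least 4 points (three free parameters).  Non-convergent or degenerate
    flat responses raise with diagnostics.
    """
    if len(series) < 4:
        raise ValueError("at least 4 titration points are required for the Hill fit")
    c = series.concentrations
    y = series.response
    if np.ptp(y) <= 0:
        raise ValueError("degenerate flat response: Hill fit is unidentifiable")

    a0 = max(float(y.max()), 1e-6)
    k0 = float(np.sqrt(c[0] * c[-1]))  # geometric mid-concentration
    p0 = (a0, k0, 1.0)
    try:
        popt, _ = curve_fit(
            _hill_curve,
            c,
            y,
            p0=p0,
            bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 50.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise ValueError(f"Hill fit failed to converge: {exc}") from exc
    amplitude, k_a, n = (float(v) for v in popt)
    rss = float(np.sum((y - _hill_curve(c, *popt)) ** 2))
    return BindingFit(model="hill", k=k_a, hill_n=n, amplitude=amplitude, rss=rss)


def k_app_from_rct(
    rct: float,
    electrode_diameter: float = 2e-3,
    redox_concentration: float = 10.0,
    temperature: float = 298.0,
    n_electrons: int = 1,
) -> float:
    """Apparent electron-transfer rate constant (m s⁻¹) from R_ct.

    k_app = R T / (n² F² A C R_ct) with disk area A = π (d/2)².  Inputs in
    SI units: diameter in m, redox concentration in mol m⁻³ (10 mol m⁻³ =
    10 mM), temperature in K.  Inversely proportional to R_ct, so the ratio
    of two rate constants equals the inverse ratio of the resistances.
    """
    if rct <= 0:
        raise ValueError("rct must be > 0")
    if electrode_diameter <= 0 or redox_concentration <= 0 or temperature <= 0 or n_electrons <= 0:
        raise ValueError("all physical inputs must be > 0")
    area = np.pi * (electrode_diameter / 2.0) ** 2
    return GAS_CONSTANT * temperature / (
        n_electrons**2 * FARADAY**2 * area * redox_concentration * rct
    )


def mass_to_molar(mass_conc: float, molecular_weight: float) -> float:
    """Convert μg mL⁻¹ to nM given the molecular weight in kDa.

    μg mL⁻¹ = mg L⁻¹; dividing by kDa (kg mol⁻¹) gives μM, i.e. 1000 nM per
    unit, so the result is ``mass_conc / molecular_weight * 1000``.
    """
    if mass_conc <= 0 or molecular_weight <= 0:
        raise ValueError("mass concentration and molecular weight must be > 0")
    return mass_conc / molecular_weight * 1000.0


def ferrocene_coverage(
    vgram: Voltammogram,
    baseline_window: Sequence[tuple[float, float]],
    n_electrons: int = 1,
) -> float:
    """Surface coverage (mol) from a surface-confined voltammetric peak.

    Fits a cubic polynomial to the current inside the ``baseline_window``
    potential ranges (which must exclude the peak), subtracts it, and
    integrates the residual faradaic current over time
    (Q = ∫ i dE / scan_rate).  Coverage is Γ = Q / (n F), assuming
    ``n_electrons`` transferred per surface-bound molecule.
    """
    if n_electrons <= 0:
        raise ValueError("n_electrons must be > 0")
    e = vgram.potential
    i = vgram.current
    mask = np.zeros(e.shape, dtype=bool)
    for lo, hi in baseline_window:
        mask |= (e >= min(lo, hi)) & (e <= max(lo, hi))
    if mask.sum() < 4:
        raise ValueError(
            f"only {int(mask.sum())} baseline points; >= 4 are needed for a cubic fit"
        )
    baseline = np.polynomial.Polynomial.fit(e[mask], i[mask], deg=3)
    faradaic = i - baseline(e)
    charge = np.trapezoid(faradaic, e) / vgram.scan_rate
    return float(charge / (n_electrons * FARADAY))
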