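"""Forward impedance model of the modified Randles circuit.

The circuit is the standard modified Randles topology: the solution
resistance ``R_s`` in series with a parallel combination of (i) a constant
phase element (CPE) representing the distributed double-layer capacitance
and (ii) the faradaic branch, i.e. the charge-transfer resistance ``R_ct``
in series with a semi-infinite Warburg diffusion element.

Sign convention: capacitive impedance carries a negative imaginary part;
Nyquist plots are conventionally drawn as ``-Im(Z)`` vs ``Re(Z)``.  Phase is
stored in radians everywhere inside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "CircuitParameters",
    "ImpedanceSpectrum",
    "cpe_impedance",
    "warburg_impedance",
    "randles_impedance",
    "spectrum_from_model",
    "to_polar",
    "polar_to_cartesian",
    "log_frequency_grid",
]

#: Canonical parameter ordering used by vectors, fits and posterior draws.
PARAM_NAMES = ("R_s", "R_ct", "Z_w", "Q", "alpha", "sigma1", "sigma2")


@dataclass(frozen=True)
class CircuitParameters:
    """The five circuit parameters plus the two polar noise parameters.

    Attributes
    ----------
    R_s : float
        Solution resistance (Ω).
    R_ct : float
        Charge-transfer resistance (Ω) — the biosensor's reporter quantity.
    Z_w : float
        Warburg coefficient (Ω·s^(-1/2)) of the semi-infinite diffusion
        element.
    Q : float
        CPE magnitude (Ω⁻¹·s^α).
    alpha : float
        CPE exponent, 0 < alpha <= 1; alpha = 1 is an ideal capacitor.
    sigma1 : float
        Standard deviation of the Gaussian noise on the impedance phase
        (radians).
    sigma2 : float
        Standard deviation of the Gaussian noise on the impedance magnitude
        (Ω).
    """

    R_s: float
    R_ct: float
    Z_w: float
    Q: float
    alpha: float
    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        for name in ("R_s", "R_ct", "Z_w", "Q", "sigma1", "sigma2"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha!r}")

    def as_array(self) -> np.ndarray:
        """Return the parameters as a 7-vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CircuitParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected a {len(PARAM_NAMES)}-vector, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def replace(self, **changes: float) -> "CircuitParameters":
        fields = {n: getattr(self, n) for n in PARAM_NAMES}
        fields.update(changes)
        return CircuitParameters(**fields)


@dataclass
class ImpedanceSpectrum:
    """A measured or simulated impedance spectrum on a frequency grid.

    ``frequencies`` must be strictly monotone (either sweep direction);
    ``z_real``/``z_imag`` are the Cartesian impedance components in Ω.
    ``metadata`` may carry DC potential ``e_dc_v``, AC amplitude ``e_ac_v``
    and equilibration time ``t_equil_s``.
    """

    frequencies: np.ndarray
    z_real: np.ndarray
    z_imag: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z_real = np.asarray(self.z_real, dtype=float)
        self.z_imag = np.asarray(self.z_imag, dtype=float)
        if self.frequencies.ndim != 1 or len(self.frequencies) == 0:
            raise ValueError("frequencies must be a non-empty 1-d array")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be strictly positive")
        diffs = np.diff(self.frequencies)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("frequencies must be strictly monotone")
        if self.z_real.shape != self.frequencies.shape or self.z_imag.shape != self.frequencies.shape:
            raise ValueError("z_real and z_imag must match the frequency grid length")
        if np.any(self.magnitude <= 0):
            raise ValueError("impedance magnitude must be strictly positive")

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self) -> Iterator[tuple[float, complex]]:
        for f, zr, zi in zip(self.frequencies, self.z_real, self.z_imag):
            yield f, complex(zr, zi)

    @property
    def z(self) -> np.ndarray:
        """Complex impedance array."""
        return self.z_real + 1j * self.z_imag

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.z_real, self.z_imag)

    @property
    def phase(self) -> np.ndarray:
        """Phase in radians, in (-π, π]."""
        return np.arctan2(self.z_imag, self.z_real)

    def nyquist(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(Re(Z), -Im(Z))`` for Nyquist plotting."""
        return self.z_real.copy(), -self.z_imag


def cpe_impedance(Q: float, alpha: float, omega) -> complex | np.ndarray:
    """Impedance of a constant phase element, ``1 / (Q (jω)^α)``.

    For ``alpha = 1`` this is an ideal capacitor ``1/(jωC)``; as
    ``alpha → 0`` it tends to a resistor of value ``1/Q``.
    """
    omega = np.asarray(omega, dtype=float)
    if Q <= 0:
        raise ValueError(f"Q must be > 0, got {Q!r}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha!r}")
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    return 1.0 / (Q * (1j * omega) ** alpha)


def warburg_impedance(Z_w: float, omega) -> complex | np.ndarray:
    """Semi-infinite Warburg impedance ``Z_w ω^(-1/2) (1 - j)``.

    The phase is exactly -45° at every frequency, producing the low-frequency
    diffusion tail of the Nyquist plot.
    """
    omega = np.asarray(omega, dtype=float)
    if Z_w <= 0:
        raise ValueError(f"Z_w must be > 0, got {Z_w!r}")
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    return Z_w * omega ** -0.5 * (1.0 - 1.0j)


def randles_impedance(params: CircuitParameters, omega) -> complex | np.ndarray:
    """Total impedance of the modified Randles circuit at angular frequency ω.

    ``Z = R_s + [ 1/Z_CPE + 1/(R_ct + Z_W) ]^(-1)`` — the CPE in parallel
    with the faradaic branch, all in series with the solution resistance.
    """
    z_cpe = cpe_impedance(params.Q, params.alpha, omega)
    z_far = params.R_ct + warburg_impedance(params.Z_w, omega)
    return params.R_s + 1.0 / (1.0 / z_cpe + 1.0 / z_far)


def spectrum_from_model(params: CircuitParameters, frequencies) -> ImpedanceSpectrum:
    """Noiseless spectrum of the circuit on the given frequency grid (Hz)."""
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size == 0:
        raise ValueError("frequency grid is empty")
    z = randles_impedance(params, 2.0 * np.pi * frequencies)
    z = np.atleast_1d(z)
    return ImpedanceSpectrum(frequencies, z.real, z.imag)


def to_polar(spectrum: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Bode (polar) form: ``(|Z| in Ω, φ in radians)``."""
    return spectrum.magnitude, spectrum.phase


def polar_to_cartesian(magnitude, phase) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_polar`; lossless to floating tolerance."""
    magnitude = np.asarray(magnitude, dtype=float)
    phase = np.asarray(phase, dtype=float)
    return magnitude * np.cos(phase), magnitude * np.sin(phase)


def log_frequency_grid(
    f_min: float = 0.05, f_max: float = 1.0e4, points_per_decade: int = 10
) -> np.ndarray:
    """Logarithmically spaced frequency grid between ``f_min`` and ``f_max``.

    The number of points is ``round(ppd · log10(f_max/f_min)) + 1`` so that a
    10 pts/decade sweep of the instrument range 0.05 Hz–10 kHz yields the
    usual 54-point grid, and whole-decade ranges get exact per-decade spacing.
    """
    if f_min <= 0 or f_max <= f_min:
        raise ValueError("require 0 < f_min < f_max")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    n = int(round(points_per_decade * np.log10(f_max / f_min))) + 1
    return np.logspace(np.log10(f_min), np.log10(f_max), max(n, 2))
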