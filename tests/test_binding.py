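"""Binding isotherms, rate-constant conversion and voltammetric coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eisfit import (
    TitrationSeries,
    Voltammogram,
    ferrocene_coverage,
    hill_fit,
    k_app_from_rct,
    langmuir_kd,
    mass_to_molar,
)
from eisfit.binding import FARADAY


def langmuir_series(kd: float, concentrations, rct_0: float = 1e4) -> TitrationSeries:
    c = np.asarray(concentrations, dtype=float)
    return TitrationSeries(rct_0=rct_0, concentrations=c, rct=rct_0 * (1 + c / kd))


def hill_series(a: float, ka: float, n: float, concentrations, rct_0: float = 1e4) -> TitrationSeries:
    c = np.asarray(concentrations, dtype=float)
    y = a * c**n / (ka**n + c**n)
    return TitrationSeries(rct_0=rct_0, concentrations=c, rct=rct_0 * (1 + y))


class TestLangmuir:
    def test_exact_recovery_from_construction(self):
        fit = langmuir_kd(langmuir_series(6.3, [15, 20, 25, 30]))
        assert fit.model == "langmuir"
        assert fit.k == pytest.approx(6.3, rel=1e-12)

    def test_doubling_response_halves_kd(self):
        series = langmuir_series(6.3, [15, 20, 25, 30])
        doubled = TitrationSeries(
            rct_0=series.rct_0,
            concentrations=series.concentrations,
            rct=series.rct_0 * (1 + 2 * series.response),
        )
        assert langmuir_kd(doubled).k == pytest.approx(6.3 / 2, rel=1e-12)

    def test_noisy_recovery_within_20_percent(self):
        rng = np.random.default_rng(6)
        series = langmuir_series(6.3, [15, 20, 25, 30])
        noisy = TitrationSeries(
            rct_0=series.rct_0,
            concentrations=series.concentrations,
            rct=series.rct * (1 + rng.normal(0, 0.1, size=4)),
        )
        assert langmuir_kd(noisy).k == pytest.approx(6.3, rel=0.20)

    def test_rescaling_resistances_is_invariant(self):
        series = langmuir_series(6.3, [15, 20, 25, 30])
        scaled = TitrationSeries(
            rct_0=series.rct_0 * 7.5, concentrations=series.concentrations, rct=series.rct * 7.5
        )
        assert langmuir_kd(scaled).k == pytest.approx(langmuir_kd(series).k, rel=1e-12)

    def test_no_binding_signal_raises(self):
        series = TitrationSeries(
            rct_0=1e4, concentrations=np.array([10.0, 20.0]), rct=np.array([9e3, 8e3])
        )
        with pytest.raises(ValueError, match="slope"):
            langmuir_kd(series)

    def test_too_few_points_rejected(self):
        series = TitrationSeries(rct_0=1e4, concentrations=np.array([10.0]), rct=np.array([1.1e4]))
        with pytest.raises(ValueError):
            langmuir_kd(series)


class TestHill:
    def test_noiseless_recovery_within_one_percent(self):
        fit = hill_fit(hill_series(3.0, 18.5, 5.7, [10, 14, 18, 22, 26, 30]))
        assert fit.amplitude == pytest.approx(3.0, rel=0.01)
        assert fit.k == pytest.approx(18.5, rel=0.01)
        assert fit.hill_n == pytest.approx(5.7, rel=0.01)

    def test_nests_langmuir_when_n_is_one(self):
        # With n = 1 and a large plateau the Hill curve reduces toward the
        # linear Langmuir regime at low saturation.
        c = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        kd = 100.0
        series = hill_series(1.0, kd, 1.0, c)
        fit = hill_fit(series)
        assert fit.hill_n == pytest.approx(1.0, rel=0.05)
        # Langmuir linearization on the same weakly-saturating data.
        langmuir = langmuir_kd(series)
        assert langmuir.k == pytest.approx(fit.k / fit.amplitude, rel=0.05)

    def test_half_occupation_at_ka(self):
        fit = hill_fit(hill_series(3.0, 18.5, 5.7, [10, 14, 18, 22, 26, 30]))
        response_at_ka = fit.amplitude * fit.k**fit.hill_n / (fit.k**fit.hill_n + fit.k**fit.hill_n)
        assert response_at_ka == pytest.approx(fit.amplitude / 2)

    def test_flat_response_rejected(self):
        series = TitrationSeries(
            rct_0=1e4,
            concentrations=np.array([10.0, 20.0, 30.0, 40.0]),
            rct=np.full(4, 1.2e4),
        )
        with pytest.raises(ValueError, match="flat"):
            hill_fit(series)


class TestKApp:
    def test_reproduces_printed_rate_constants(self):
        # Mean bare-electrode R_ct 2.8 kΩ and modified-electrode 34.2 kΩ on
        # a 2 mm disk in 10 mM ferricyanide at room temperature.
        k_bare = k_app_from_rct(2.8e3, 2e-3, 10.0, 298.0, 1)
        k_mod = k_app_from_rct(34.2e3, 2e-3, 10.0, 298.0, 1)
        assert k_bare * 1e6 == pytest.approx(3.0, abs=0.05)
        assert k_mod * 1e6 == pytest.approx(0.2, abs=0.05)

    def test_rate_ratio_matches_inverse_resistance_ratio(self):
        k1 = k_app_from_rct(2.8e3)
        k2 = k_app_from_rct(34.2e3)
        assert k1 / k2 == pytest.approx(34.2 / 2.8, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(rct=st.floats(1.0, 1e7), factor=st.floats(1.1, 100.0))
    def test_inverse_proportionality(self, rct, factor):
        assert k_app_from_rct(rct) == pytest.approx(
            factor * k_app_from_rct(rct * factor), rel=1e-9
        )

    def test_non_positive_rct_rejected(self):
        with pytest.raises(ValueError):
            k_app_from_rct(0.0)


class TestMassToMolar:
    @pytest.mark.parametrize(
        "mass,mw,expected",
        [(6.3, 26.0, 242.30769230769232), (26.0, 26.0, 1000.0), (18.5, 26.0, 711.5384615384615)],
    )
    def test_known_conversions(self, mass, mw, expected):
        assert mass_to_molar(mass, mw) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mass_to_molar(-1.0, 26.0)


class TestFerroceneCoverage:
    BASELINE = [(0.0, 0.08), (0.42, 0.5)]

    @staticmethod
    def make_trace(charge: float, scan_rate: float = 0.1, noise: float = 0.0, seed: int = 0):
        e = np.linspace(0.0, 0.5, 600)
        background = 1e-6 + 2e-6 * e - 3e-6 * e**2 + 4e-6 * e**3
        width = 0.03
        peak = charge * scan_rate / (width * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((e - 0.25) / width) ** 2
        )
        current = background + peak
        if noise > 0:
            current = current + np.random.default_rng(seed).normal(0, noise, size=e.shape)
        return Voltammogram(potential=e, current=current, scan_rate=scan_rate)

    def test_constructed_trace_round_trip(self):
        charge = 0.35e-12 * FARADAY  # 0.35 pmol of one-electron transfers
        vgram = self.make_trace(charge)
        gamma = ferrocene_coverage(vgram, self.BASELINE)
        assert gamma == pytest.approx(0.35e-12, rel=0.02)

    def test_zero_current_gives_zero_coverage(self):
        vgram = Voltammogram(np.linspace(0, 0.5, 100), np.zeros(100), 0.1)
        assert ferrocene_coverage(vgram, self.BASELINE) == pytest.approx(0.0, abs=1e-18)

    def test_linearity_in_peak_current(self):
        g1 = ferrocene_coverage(self.make_trace(1e-8), self.BASELINE)
        g2 = ferrocene_coverage(self.make_trace(2e-8), self.BASELINE)
        assert g2 == pytest.approx(2 * g1, rel=1e-6)

    def test_exact_for_any_cubic_background(self):
        # A pure cubic background must be removed to quadrature accuracy.
        e = np.linspace(0.0, 0.5, 400)
        background = -5e-6 + 4e-6 * e + 8e-6 * e**2 - 9e-6 * e**3
        vgram = Voltammogram(e, background, 0.1)
        assert abs(ferrocene_coverage(vgram, self.BASELINE)) < 1e-18

    def test_too_few_baseline_points_rejected(self):
        vgram = self.make_trace(1e-9)
        with pytest.raises(ValueError, match="baseline"):
            ferrocene_coverage(vgram, [(-1.0, -0.9)])
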