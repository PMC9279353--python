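import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from guvflux.calibration import (BufferComponent, BufferSystem,
                                 CalibrationCurve, CalibrationRangeError,
                                 acid_to_titrate, buffer_capacity,
                                 intensity_to_ph, interpolate_table,
                                 ph_to_intensity)
from guvflux.constants import water_ion_product

LN10 = math.log(10.0)


class TestCalibrationCurve:
    def test_midpoint_of_titration(self, curve):
        mid = ph_to_intensity(curve.apparent_pKa, curve)
        assert mid == pytest.approx((curve.I_min + curve.I_max) / 2)

    def test_asymptotes(self, curve):
        assert ph_to_intensity(-50.0, curve) == pytest.approx(curve.I_min)
        assert ph_to_intensity(50.0, curve) == pytest.approx(curve.I_max)

    def test_sigmoid_value_at_window_edge(self):
        # I_min=0, I_max=1000, pKa=7.3 at pH 7.6: 1000/(1+10^-0.3)
        c = CalibrationCurve(apparent_pKa=7.3, I_min=0.0, I_max=1000.0)
        assert ph_to_intensity(7.6, c) == pytest.approx(
            1000.0 / (1.0 + 10.0 ** -0.3))
        assert ph_to_intensity(7.6, c) == pytest.approx(666.1, abs=0.1)

    def test_strictly_increasing(self, curve):
        pH = np.linspace(3, 11, 400)
        assert np.all(np.diff(ph_to_intensity(pH, curve)) > 0)

    @given(st.floats(min_value=6.01, max_value=7.59))
    def test_round_trip_in_window(self, pH):
        c = CalibrationCurve()
        back, ok = intensity_to_ph(ph_to_intensity(pH, c), c)
        assert back == pytest.approx(pH, abs=1e-10)
        assert ok

    def test_quench_boundary_raises(self, curve):
        with pytest.raises(CalibrationRangeError, match="quench"):
            intensity_to_ph(curve.I_min, curve)
        with pytest.raises(CalibrationRangeError):
            intensity_to_ph(curve.I_max + 1.0, curve)

    def test_below_window_flagged_unresolvable(self, curve):
        I = ph_to_intensity(5.5, curve)
        pH, ok = intensity_to_ph(I, curve)
        assert pH == pytest.approx(5.5, abs=1e-9)
        assert not ok

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(I_min=10.0, I_max=5.0)


def _titration_oracle_beta(pH_targets, components, temperature=294.15):
    """Independent buffer-capacity oracle: solve the full charge-balance
    equilibrium for a grid of added strong acid, then differentiate the
    acid-vs-pH curve numerically."""
    kw = water_ion_product(temperature)

    def charge_balance(H, C_acid, Na):
        # Na+ + H+ = OH- + sum(deprotonated buffer) + A-(strong acid)
        rhs = kw / H + C_acid
        for _, pKa, C in components:
            Ka = 10.0 ** (-pKa) / 1000.0
            rhs += C * Ka / (Ka + H)
        return Na + H - rhs

    # Na+ fixed by requiring pH 7.6 before any acid is added
    H0 = 10.0 ** -7.6 / 1000.0
    Na = -charge_balance(H0, 0.0, 0.0)

    def ph_of_acid(C_acid):
        H = brentq(charge_balance, 1e-17, 1e-4, args=(C_acid, Na),
                   xtol=1e-22, rtol=8.9e-16)
        return -math.log10(H * 1000.0)

    out = []
    for pH in pH_targets:
        # invert pH -> acid, then central difference of acid vs pH
        C = brentq(lambda c: ph_of_acid(c) - pH, -1e-4, 1e-4, xtol=1e-18)
        eps = 1e-9
        dpH = ph_of_acid(C - eps) - ph_of_acid(C + eps)
        out.append(2 * eps / dpH)
    return np.array(out)


class TestBufferCapacity:
    def test_titration_maximum_identity(self):
        # single component at pH = pKa: beta = ln10 * C / 4
        buf = BufferSystem(components=(BufferComponent("X", 7.0, 1e-5),))
        assert buffer_capacity(7.0, buf) == pytest.approx(
            LN10 * 1e-5 / 4, rel=1e-3)

    def test_pure_water(self):
        buf = BufferSystem(components=(), temperature=298.15)
        # at pH 7, 25 degC: ln10 * ([H+] + Kw/[H+]) ~ ln10 * 2e-10
        assert buffer_capacity(7.0, buf) == pytest.approx(4.6e-10, rel=0.02)

    def test_linear_in_concentration(self, buffer):
        b1 = buffer_capacity(7.2, buffer)
        double = BufferSystem(components=(
            BufferComponent("HEPES", 7.5, 2e-5),), temperature=294.15)
        water = buffer_capacity(7.2, BufferSystem(temperature=294.15))
        assert buffer_capacity(7.2, double) - water == pytest.approx(
            2 * (b1 - water), rel=1e-9)

    def test_against_titration_oracle(self, buffer):
        """Closed form vs brute-force charge-balance titration, pH 6-8."""
        pH = np.linspace(6.0, 8.0, 9)
        oracle = _titration_oracle_beta(pH, [("HEPES", 7.5, 1e-5)])
        closed = buffer_capacity(pH, buffer)
        assert np.all(np.abs(closed / oracle - 1) < 1e-3)

    def test_rejects_out_of_range_ph(self, buffer):
        with pytest.raises(ValueError):
            buffer_capacity(-1.0, buffer)

    def test_tabulated_beta_override(self):
        tab = np.array([[5.0, 3e-6], [9.0, 3e-6]])
        buf = BufferSystem.with_beta_table(tab)
        assert buffer_capacity(7.0, buf) == pytest.approx(3e-6)
        assert interpolate_table(7.0, tab) == pytest.approx(3e-6)


class TestTitration:
    def test_strong_acid_matches_beta_integral(self, buffer):
        # for a small pH step the acid needed is ~ beta * dpH
        got = acid_to_titrate(buffer, 7.6, 7.59)
        assert got == pytest.approx(buffer_capacity(7.595, buffer) * 0.01,
                                    rel=1e-3)

    def test_weak_acid_needs_more_than_strong(self, buffer):
        strong = acid_to_titrate(buffer, 7.6, 7.0)
        weak = acid_to_titrate(buffer, 7.6, 7.0, acid_pKa=3.75)
        assert weak > strong
        assert weak == pytest.approx(strong, rel=1e-3)  # ~fully dissociated
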