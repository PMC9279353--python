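from dataclasses import replace

import numpy as np
import pytest

from guvflux.calibration import BufferSystem
from guvflux.fluxes import (build_flux_profile, compute_flux,
                            cumulative_permeated_protons,
                            fit_permeability_linear, smooth_series)


@pytest.fixture()
def const_beta_buffer():
    """Buffer with a flat beta(pH) = 5e-6 mol/cm^3/pH table."""
    return BufferSystem.with_beta_table(
        np.array([[3.0, 5e-6], [11.0, 5e-6]]))


class TestCumulativeProtons:
    def test_constant_ph_gives_zeros(self, buffer):
        out = cumulative_permeated_protons(np.full(20, 7.2), buffer)
        np.testing.assert_array_equal(out, np.zeros(20))

    def test_single_step_arithmetic(self, const_beta_buffer):
        out = cumulative_permeated_protons(np.array([7.60, 7.50]),
                                           const_beta_buffer)
        assert out[-1] == pytest.approx(5e-7)

    def test_simulator_round_trip(self, strong_trace, buffer):
        got = cumulative_permeated_protons(strong_trace.pH_i, buffer)
        assert got[-1] == pytest.approx(strong_trace.cum_protons[-1],
                                        rel=0.01)

    def test_needs_two_frames(self, buffer):
        with pytest.raises(ValueError):
            cumulative_permeated_protons(np.array([7.0]), buffer)


class TestSmoothing:
    def test_reproduces_polynomials_exactly(self):
        t = np.arange(50, dtype=float)
        for y in (np.full(50, 3.2), 1.5 * t - 4.0, 0.1 * t**2 - t + 2):
            np.testing.assert_allclose(smooth_series(y, 11, 2), y,
                                       atol=1e-9 * max(1, abs(y).max()))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.zeros(20), window=8)
        with pytest.raises(ValueError):
            smooth_series(np.zeros(20), window=3, order=3)
        with pytest.raises(ValueError):
            smooth_series(np.zeros(5), window=9)

    def test_noise_suppression_on_quadratic(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 200)
        truth = 3 * t**2 - t
        noisy = truth + rng.normal(0, 0.05, t.size)
        sm = smooth_series(noisy, 15, 2)
        assert np.sqrt(np.mean((sm - truth) ** 2)) < \
            np.sqrt(np.mean((noisy - truth) ** 2)) / 2


class TestComputeFlux:
    def test_constant_cumulative_gives_zero(self):
        t = np.arange(10, dtype=float)
        np.testing.assert_allclose(compute_flux(np.full(10, 2e-7), t, 1e-3),
                                   np.zeros(10), atol=1e-25)

    def test_linear_ramp(self):
        t = np.arange(20, dtype=float)
        k = 3e-9
        J = compute_flux(k * t, t, 1.2e-3)
        np.testing.assert_allclose(J, k * 1.2e-3 / 3, rtol=1e-12)

    def test_non_monotonic_times_rejected(self):
        with pytest.raises(ValueError):
            compute_flux(np.zeros(5), np.array([0.0, 1, 1, 2, 3]), 1e-3)

    def test_clamped_simulation_flux_recovery(self, clamped_trace, buffer):
        """Reconstructed flux matches P*delta_H within 2% away from edges."""
        prof = build_flux_profile(clamped_trace.times, clamped_trace.pH_i,
                                  clamped_trace.pH_o, buffer,
                                  clamped_trace.radius)
        fick = 1.9e-3 * prof.delta_H
        inner = slice(4, -4)
        np.testing.assert_allclose(prof.J[inner], fick[inner], rtol=0.02)


class TestBuildProfile:
    def test_pre_arrival_only_is_an_error(self, buffer):
        t = np.arange(0, 50, 5.0)
        with pytest.raises(ValueError, match="no resolvable window"):
            build_flux_profile(t, np.full(10, 7.6), np.full(10, 7.6),
                               buffer, 1e-3)

    def test_quench_crossing_truncates(self, buffer):
        t = np.arange(0, 200, 5.0)
        pH_o = np.linspace(7.6, 5.5, t.size)  # crosses 6.0
        pH_i = np.linspace(7.6, 7.4, t.size)
        k = int(np.argmax(pH_o <= 6.0))
        prof = build_flux_profile(t, pH_i, pH_o, buffer, 1e-3)
        assert len(prof.times) <= k
        assert np.all(prof.pH_o > 6.0)

    def test_profile_matches_ground_truth(self, strong_trace, buffer):
        prof = build_flux_profile(strong_trace.times, strong_trace.pH_i,
                                  strong_trace.pH_o, buffer,
                                  strong_trace.radius)
        idx = np.searchsorted(strong_trace.times, prof.times)
        truth = strong_trace.J_Hplus[idx] + strong_trace.J_HA[idx]
        inner = slice(4, -4)
        np.testing.assert_allclose(prof.J[inner], truth[inner], rtol=0.05)
        assert prof.V_over_A == pytest.approx(strong_trace.radius / 3)

    def test_clamped_profile_is_linear(self, clamped_trace, buffer):
        prof = build_flux_profile(clamped_trace.times, clamped_trace.pH_i,
                                  clamped_trace.pH_o, buffer,
                                  clamped_trace.radius)
        est = fit_permeability_linear([prof], linear_fraction=1.0)
        assert est.r_squared > 0.999


class TestPermeabilityFit:
    def _profile_from_line(self, P=2e-3, n=30):
        t = np.arange(n, dtype=float) * 5
        delta_H = np.linspace(1e-12, 5e-11, n)
        from guvflux.fluxes import FluxProfile

        return FluxProfile(vesicle_id=0, times=t, delta_H=delta_H,
                           J=P * delta_H, pH_i=np.full(n, 7.55),
                           pH_o=np.linspace(7.55, 7.3, n), radius=1e-3)

    def test_exact_line_recovered_with_zero_se(self):
        prof = self._profile_from_line(P=2e-3)
        est = fit_permeability_linear([prof], linear_fraction=1.0)
        assert est.P == pytest.approx(2e-3, rel=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-15)

    def test_regime_gate_excludes_fast_frames(self):
        prof = self._profile_from_line()
        fast = replace(prof, pH_i=np.linspace(7.5, 1.7, len(prof.times)))
        with pytest.raises(ValueError, match="qualifying points"):
            fit_permeability_linear([fast], dpH_threshold=0.1,
                                    linear_fraction=1.0)

    def test_too_few_points_rejected(self):
        prof = self._profile_from_line(n=30)
        short = replace(prof, delta_H=np.full(30, -1.0))  # no positive gradient
        with pytest.raises(ValueError):
            fit_permeability_linear([short])

    def test_pipeline_recovery_within_tolerance(self, strong_trace, buffer):
        prof = build_flux_profile(strong_trace.times, strong_trace.pH_i,
                                  strong_trace.pH_o, buffer,
                                  strong_trace.radius)
        est = fit_permeability_linear([prof])
        assert est.P == pytest.approx(1.9e-3, rel=0.15)

    def test_saturation_visible_at_large_gradient(self, strong_trace, buffer):
        """Unclamped flux at the largest gradient is well below Fick."""
        prof = build_flux_profile(strong_trace.times, strong_trace.pH_i,
                                  strong_trace.pH_o, buffer,
                                  strong_trace.radius)
        k = int(np.argmax(prof.delta_H))
        ratio = prof.J[k] / (1.9e-3 * prof.delta_H[k])
        assert ratio < 0.9
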