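"""Detector-trace corrections and headspace deconvolution."""

import numpy as np
import pytest

from isoresp.respirometry import (
    DetectorTimeSeries,
    FluxSeries,
    RateSeries,
    TrapWindow,
    VesselGeometry,
    baseline_correct,
    carbon_flux_to_ppm,
    deconvolve_headspace,
    integrate_window,
    ppm_to_carbon_flux,
    rescale_to_manometric,
    simulate_headspace,
)

R_GAS = 8.31446261815324


def gaussian_pulse(time, peak_t=900.0, width=240.0, amplitude=5.0):
    return amplitude * np.exp(-0.5 * ((time - peak_t) / width) ** 2)


def compact_pulse(time, peak_t=900.0, width=240.0, amplitude=5.0):
    """Gaussian pulse hard-truncated to zero beyond 4 widths (exactly flat tails)."""
    p = gaussian_pulse(time, peak_t, width, amplitude)
    return np.where(np.abs(time - peak_t) <= 4 * width, p, 0.0)


@pytest.fixture()
def geometry():
    return VesselGeometry(
        vessel_volume=3.0, medium_volume_schedule=((0.0, 2.0),), flow=100.0
    )


class TestBaselineCorrect:
    def _series(self, ppm):
        t = np.arange(ppm.size, dtype=float)
        return DetectorTimeSeries(time=t, co2_ppm=ppm)

    def test_zero_baseline_unchanged(self):
        t = np.arange(3000.0)
        pulse = compact_pulse(t, peak_t=1400.0, width=120.0)
        s = self._series(pulse)
        out = baseline_correct(s, (0.0, 100.0), (2800.0, 2999.0))
        assert out.co2_ppm == pytest.approx(pulse, abs=1e-9)

    def test_constant_offset_removed(self):
        t = np.arange(3000.0)
        pulse = compact_pulse(t, peak_t=1400.0, width=120.0)
        s = self._series(pulse + 17.5)
        out = baseline_correct(s, (0.0, 100.0), (2800.0, 2999.0))
        assert out.co2_ppm == pytest.approx(pulse, abs=1e-6)

    def test_linear_drift_removed_to_1pct_of_peak(self):
        t = np.arange(4000.0)
        pulse = gaussian_pulse(t, peak_t=1000.0, width=200.0, amplitude=80.0)
        drift = 3.0 + 0.004 * t
        s = self._series(pulse + drift)
        out = baseline_correct(s, (0.0, 150.0), (3700.0, 3999.0))
        assert np.max(np.abs(out.co2_ppm - pulse)) < 0.01 * pulse.max()

    def test_window_on_pulse_warns(self):
        t = np.arange(3000.0)
        pulse = gaussian_pulse(t, peak_t=900.0, width=150.0, amplitude=100.0)
        s = self._series(pulse + np.random.default_rng(0).normal(0, 0.1, t.size))
        with pytest.warns(UserWarning, match="anchor window"):
            baseline_correct(s, (800.0, 1000.0), (2800.0, 2999.0))

    def test_too_few_samples_rejected(self):
        s = self._series(np.zeros(100))
        with pytest.raises(ValueError, match="at least 3"):
            baseline_correct(s, (0.0, 1.0), (90.0, 99.0))


class TestUnitBridge:
    def test_zero_ppm_zero_flux(self):
        s = DetectorTimeSeries(time=np.arange(10.0), co2_ppm=np.zeros(10))
        assert ppm_to_carbon_flux(s).flux == pytest.approx(np.zeros(10))

    def test_ideal_gas_oracle(self):
        """1000 ppm at 100 mL/min, 298.15 K, 101.325 kPa ≈ 49.1 µg C/min,
        recomputed here from first principles."""
        s = DetectorTimeSeries(
            time=np.arange(5.0), co2_ppm=np.full(5, 1000.0),
            flow=100.0, temperature=298.15, pressure=101.325,
        )
        # independent hand calculation: mol CO2/min = x * Q * n/V
        mol_per_L = 101.325e3 / (R_GAS * 298.15) / 1000.0
        expected = 1000e-6 * 0.1 * mol_per_L * 12.011 * 1e6
        assert expected == pytest.approx(49.1, abs=0.05)
        assert ppm_to_carbon_flux(s).flux[0] == pytest.approx(expected, rel=1e-12)

    def test_flow_linearity(self):
        t = np.arange(10.0)
        ppm = np.linspace(0, 500, 10)
        f1 = ppm_to_carbon_flux(DetectorTimeSeries(t, ppm, flow=100.0))
        f2 = ppm_to_carbon_flux(DetectorTimeSeries(t, ppm, flow=200.0))
        assert f2.flux == pytest.approx(2.0 * f1.flux)

    def test_inverse_round_trip(self):
        t = np.arange(100.0)
        flux = FluxSeries(t, gaussian_pulse(t, 50.0, 10.0, 3.0))
        back = ppm_to_carbon_flux(carbon_flux_to_ppm(flux))
        assert back.flux == pytest.approx(flux.flux, rel=1e-12)


class TestIntegrateWindow:
    def test_constant_flux(self):
        t = np.arange(0.0, 101.0)
        s = FluxSeries(t, np.full(t.size, 3.0))
        assert integrate_window(s, 10.0, 60.0) == pytest.approx(150.0)

    def test_additivity_with_interior_split(self):
        t = np.arange(0.0, 500.0)
        s = FluxSeries(t, gaussian_pulse(t, 250.0, 60.0, 4.0))
        whole = integrate_window(s, 20.0, 480.0)
        parts = integrate_window(s, 20.0, 137.3) + integrate_window(s, 137.3, 480.0)
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_closed_form_pulse_oracle(self):
        """∫ A·exp(−(t−µ)²/2σ²) = A·σ·√(2π) within 0.1% at 1-min sampling."""
        t = np.arange(0.0, 3000.0)
        A, mu, sigma = 4.0, 1500.0, 120.0
        s = FluxSeries(t, A * np.exp(-0.5 * ((t - mu) / sigma) ** 2))
        expected = A * sigma * np.sqrt(2 * np.pi)
        got = integrate_window(s, 0.0, 2999.0)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_empty_window_errors(self):
        s = FluxSeries(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="empty or inverted"):
            integrate_window(s, 5.0, 5.0)

    def test_window_outside_span_errors(self):
        s = FluxSeries(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="beyond"):
            integrate_window(s, 5.0, 20.0)


class TestRescaleToManometric:
    def test_matching_integral_identity(self):
        t = np.arange(0.0, 200.0)
        s = FluxSeries(t, np.full(t.size, 2.0))
        trap = TrapWindow(10.0, 110.0, manometric_mass_ugC=200.0)
        out, qc = rescale_to_manometric(s, [trap])
        assert out.flux == pytest.approx(s.flux)
        assert qc["scale_factor"].iloc[0] == pytest.approx(1.0)

    def test_half_integral_doubles_flux(self):
        t = np.arange(0.0, 200.0)
        s = FluxSeries(t, np.full(t.size, 1.0))
        trap = TrapWindow(20.0, 120.0, manometric_mass_ugC=200.0)
        out, _ = rescale_to_manometric(s, [trap])
        inside = (t >= 20.0) & (t <= 120.0)
        assert out.flux[inside] == pytest.approx(2.0, abs=1e-12)
        assert out.flux[~inside] == pytest.approx(1.0)

    def test_random_corruptions_restored_exactly(self, rng):
        t = np.arange(0.0, 1500.0)
        base = gaussian_pulse(t, 700.0, 200.0, 3.0) + 0.2
        windows = [(0.0, 500.0), (500.0, 1000.0), (1000.0, 1499.0)]
        true_masses = [
            integrate_window(FluxSeries(t, base), a, b) for a, b in windows
        ]
        corrupted = base.copy()
        for (a, b), scale in zip(windows, rng.uniform(0.5, 1.8, 3)):
            m = (t >= a) & (t <= b)
            corrupted[m] *= scale
        traps = [
            TrapWindow(a, b, manometric_mass_ugC=mass)
            for (a, b), mass in zip(windows, true_masses)
        ]
        out, qc = rescale_to_manometric(FluxSeries(t, corrupted), traps)
        for (a, b), mass in zip(windows, true_masses):
            assert integrate_window(out, a, b) == pytest.approx(mass, rel=1e-12)
        # conservation over all windows
        total = sum(integrate_window(out, a, b) for a, b in windows)
        assert total == pytest.approx(sum(true_masses), rel=1e-12)

    def test_nonpositive_integral_errors(self):
        t = np.arange(0.0, 100.0)
        s = FluxSeries(t, np.zeros(t.size))
        with pytest.raises(ValueError, match="non-positive"):
            rescale_to_manometric(s, [TrapWindow(0.0, 99.0, 100.0)])

    def test_trap_capacity_enforced(self):
        with pytest.raises(ValueError, match="capacity"):
            TrapWindow(0.0, 100.0, manometric_mass_ugC=2500.0)


class TestHeadspaceDeconvolution:
    def test_steady_state_identity(self, geometry):
        t = np.arange(0.0, 600.0)
        f = FluxSeries(t, np.full(t.size, 4.0))
        rate = deconvolve_headspace(f, geometry)
        # S = F at steady state; per-liter rate divides by the 2 L medium
        assert rate.rate[50:-50] == pytest.approx(2.0, abs=1e-9)

    def test_forward_inverse_round_trip(self, geometry):
        """A bell-shaped source convolved forward then inverted comes back
        within 5% relative L2 error at 1-min sampling."""
        t = np.arange(0.0, 4000.0)
        source = gaussian_pulse(t, peak_t=1200.0, width=300.0, amplitude=6.0)
        f = simulate_headspace(t, source, geometry)
        rec = deconvolve_headspace(f, geometry)
        recovered_source = rec.rate * geometry.medium_volume(t)
        err = np.linalg.norm(recovered_source - source) / np.linalg.norm(source)
        assert err < 0.05

    def test_forward_consistency_of_recovered_source(self, geometry):
        t = np.arange(0.0, 3000.0)
        source = gaussian_pulse(t, 900.0, 250.0, 5.0)
        f = simulate_headspace(t, source, geometry)
        rec = deconvolve_headspace(f, geometry)
        refwd = simulate_headspace(t, rec.rate * geometry.medium_volume(t), geometry)
        err = np.linalg.norm(refwd.flux - f.flux) / np.linalg.norm(f.flux)
        assert err < 0.05

    def test_halving_medium_volume_doubles_rate(self):
        t = np.arange(0.0, 500.0)
        f = FluxSeries(t, np.full(t.size, 4.0))
        g_full = VesselGeometry(
            vessel_volume=3.0, medium_volume_schedule=((0.0, 2.0),),
            flow=100.0, headspace_volume=1.0,
        )
        g_half = VesselGeometry(
            vessel_volume=3.0, medium_volume_schedule=((0.0, 1.0),),
            flow=100.0, headspace_volume=1.0,
        )
        r_full = deconvolve_headspace(f, g_full)
        r_half = deconvolve_headspace(f, g_half)
        assert r_half.rate == pytest.approx(2.0 * r_full.rate)

    def test_source_peak_precedes_detector_peak(self, geometry, rng):
        """The compartment delays the signal: recovered source peaks no later
        than the detector flux, across random pulse shapes."""
        t = np.arange(0.0, 4000.0)
        for _ in range(5):
            source = gaussian_pulse(
                t,
                peak_t=rng.uniform(800, 2000),
                width=rng.uniform(150, 500),
                amplitude=rng.uniform(2, 10),
            )
            f = simulate_headspace(t, source, geometry)
            rec = deconvolve_headspace(f, geometry)
            assert rec.peak_time <= t[np.argmax(f.flux)] + 1e-9

    def test_window_too_small_errors(self, geometry):
        f = FluxSeries(np.arange(100.0), np.ones(100))
        with pytest.raises(ValueError, match="at least 3"):
            deconvolve_headspace(f, geometry, smooth_window=2)

    def test_negative_rates_flagged_not_clipped(self, geometry, rng):
        t = np.arange(0.0, 2000.0)
        noisy = gaussian_pulse(t, 600.0, 150.0, 2.0) + rng.normal(0, 0.3, t.size)
        f = FluxSeries(t, noisy)
        rate = deconvolve_headspace(f, geometry)
        assert rate.has_negative_rates  # noise must survive, not be clipped


class TestTimeUnitConsistency:
    def test_integral_commutes_with_unit_change(self):
        t_min = np.arange(0.0, 600.0)
        flux_per_min = gaussian_pulse(t_min, 300.0, 80.0, 4.0)
        a = integrate_window(FluxSeries(t_min, flux_per_min), 50.0, 550.0)
        # hours: time/60, flux*60
        b = integrate_window(
            FluxSeries(t_min / 60.0, flux_per_min * 60.0), 50.0 / 60.0, 550.0 / 60.0
        )
        assert b == pytest.approx(a, rel=1e-12)


class TestVesselGeometry:
    def test_schedule_must_be_non_increasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            VesselGeometry(medium_volume_schedule=((0.0, 1.5), (100.0, 2.0)))

    def test_headspace_tracks_medium_withdrawals(self):
        g = VesselGeometry(
            vessel_volume=3.0,
            medium_volume_schedule=((0.0, 2.0), (100.0, 1.8)),
        )
        assert g.headspace(50.0) == pytest.approx(1.0)
        assert g.headspace(150.0) == pytest.approx(1.2)
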