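"""Waveform statistics: features, intersecting-tangents foot, foot-to-foot
PWV, zero-padded spectra, secondary-peak search and curvature QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cathfidelity import (PressureWaveform, WaveformParams,
                          amplitude_spectrum, curvature_sum, detect_foot,
                          dicrotic_ring_spectrum, extract_features,
                          generate_pressure_waveform, measure_with_catheter,
                          pwv_foot_to_foot, secondary_peak)
from cathfidelity.errors import (DegenerateSignalError, DetectionError,
                                 ParameterError)


def steady_filtered(w, f_n, zeta, warm=2):
    """Transducer-distort a periodic record in steady state."""
    tiled = PressureWaveform(np.tile(w.samples, warm + 1), w.rate, w.t0)
    out = measure_with_catheter(tiled, f_n, zeta)
    return PressureWaveform(out.samples[warm * w.samples.size:], w.rate, w.t0)


class TestFeatures:
    def test_default_waveform_pulse_pressure(self, default_waveform):
        f = extract_features(default_waveform, 1.0)
        assert f.P_s == pytest.approx(106.4, abs=0.5)
        assert f.P_d == pytest.approx(5.54, abs=0.5)
        assert f.pulse_pressure == pytest.approx(100.86, abs=0.5)
        assert f.notch_present
        assert f.notch_time is not None

    def test_notch_lies_between_peak_and_cycle_end(self, default_waveform):
        f = extract_features(default_waveform, 1.0)
        cycle_start = np.floor(f.notch_time)
        assert cycle_start + 0.25 < f.notch_time < cycle_start + 1.0

    def test_constant_signal(self):
        w = PressureWaveform(np.full(200, 80.0), 100.0)
        f = extract_features(w, 1.0)
        assert f.P_s == f.P_d == 80.0
        assert f.pulse_pressure == 0.0
        assert not f.notch_present

    def test_no_ring_no_notch(self):
        w = generate_pressure_waveform(WaveformParams(ring_amp=0.0))
        assert not extract_features(w, 1.0).notch_present

    def test_short_record_rejected(self):
        w = PressureWaveform(np.linspace(0, 1, 50), 100.0)
        with pytest.raises(ParameterError):
            extract_features(w, 1.0)


def ramp_cycle(rate=1000.0, t_start=0.30, rise=0.10, n=1000):
    """One cycle: flat baseline, exact linear ramp starting at t_start, flat top."""
    t = np.arange(n) / rate
    y = np.where(t < t_start, 10.0,
                 np.where(t < t_start + rise, 10.0 + 50 * (t - t_start) / rise,
                          60.0))
    return PressureWaveform(y, rate)


class TestFootDetection:
    def test_exact_ramp_foot_at_ramp_start(self):
        w = ramp_cycle()
        foot = detect_foot(w, 0.0)
        assert foot == pytest.approx(0.30, abs=1.0 / w.rate)

    def test_translation_equivariance(self):
        w = ramp_cycle()
        shifted = PressureWaveform(np.roll(w.samples, 10), w.rate)  # +10 ms
        f0 = detect_foot(w, 0.0)
        f1 = detect_foot(shifted, 0.0)
        assert f1 - f0 == pytest.approx(0.010, abs=1e-4)

    def test_lowpass_delays_the_foot(self, default_waveform):
        """Heavy smoothing moves the detected foot later — the mechanism
        behind the catheter's PWV bias."""
        blurred = steady_filtered(default_waveform, 3.0, 1.5)
        f_clean = detect_foot(default_waveform, 2.0, 1.0)
        f_blur = detect_foot(blurred, 2.0, 1.0)
        assert f_blur > f_clean

    def test_flat_window_rejected(self):
        w = PressureWaveform(np.full(100, 5.0), 100.0)
        with pytest.raises(DetectionError):
            detect_foot(w, 0.0)


class TestPWV:
    def test_pure_delay_pair(self):
        """Identical waveform delayed 16.6 ms over 100 mm -> 6.02 m/s."""
        rate = 5000.0
        base = ramp_cycle(rate=rate, t_start=0.2, rise=0.05, n=5000)
        delayed = PressureWaveform(np.roll(base.samples, 83), rate)  # 16.6 ms
        r = pwv_foot_to_foot([(0.0, base), (0.1, delayed)], 0.1)
        assert r.pwv == pytest.approx(0.1 / 0.0166, rel=0.01)

    def test_three_pair_average(self):
        rate = 1000.0
        base = ramp_cycle(rate=rate)
        probes = [(0.08 * i, PressureWaveform(np.roll(base.samples, 10 * i),
                                              rate)) for i in range(4)]
        r = pwv_foot_to_foot(probes, 0.08)
        assert len(r.pairs) == 3
        assert r.pwv == pytest.approx(8.0, rel=0.01)

    def test_negative_transit_time_is_error(self):
        rate = 1000.0
        base = ramp_cycle(rate=rate)
        early = PressureWaveform(np.roll(base.samples, -20), rate)
        with pytest.raises(DetectionError, match="transit"):
            pwv_foot_to_foot([(0.0, base), (0.1, early)], 0.1)

    def test_no_pair_at_separation_is_error(self):
        base = ramp_cycle()
        with pytest.raises(DetectionError, match="no probe pair"):
            pwv_foot_to_foot([(0.0, base), (0.05, base)], 0.1)

    def test_simulated_pwv_near_moens_korteweg(self, exp_config, wire_result):
        """Foot-to-foot PWV from the simulated tube within 20% of the
        closed-form wave speed."""
        from cathfidelity import moens_korteweg_speed, pressure_at
        probes = [(x, pressure_at(wire_result, x, 1000.0))
                  for x in exp_config.probes]
        r = pwv_foot_to_foot(probes, 0.12)
        mk = moens_korteweg_speed(exp_config.vessel)
        assert abs(r.pwv - mk) / mk < 0.20


class TestSpectrum:
    def test_single_tone_identity(self):
        rate, f0, amp = 100.0, 1.0, 10.0
        t = np.arange(1000) / rate
        w = PressureWaveform(80 + amp * np.sin(2 * np.pi * f0 * t), rate)
        s = amplitude_spectrum(w, 8)
        i = np.argmax(s.amps)
        assert s.freqs[i] == pytest.approx(1.0, abs=s.freqs[1] - s.freqs[0])
        assert s.amps[i] == pytest.approx(amp, rel=0.02)

    def test_parseval_consistency(self, default_waveform):
        s = amplitude_spectrum(default_waveform, 8)
        assert s.parseval_ratio == pytest.approx(1.0, rel=0.01)

    def test_default_waveform_fundamental_is_heart_rate(self, default_waveform):
        s = amplitude_spectrum(default_waveform, 8)
        assert s.fundamental == pytest.approx(1.0, abs=0.02)

    def test_dc_only_signal_empty_after_detrend(self):
        w = PressureWaveform(np.full(500, 42.0), 100.0)
        s = amplitude_spectrum(w, 8)
        assert np.all(s.amps < 1e-9)

    def test_pad_factor_validated(self, default_waveform):
        with pytest.raises(ParameterError, match="pad_factor"):
            amplitude_spectrum(default_waveform, 0)


class TestSecondaryPeak:
    def test_default_ring_recovered(self, default_waveform):
        s = dicrotic_ring_spectrum(default_waveform, 1.0, pad_factor=32)
        pk = secondary_peak(s)
        assert pk is not None
        assert pk.freq == pytest.approx(5.4, abs=0.2)

    def test_estimator_tracks_ring_frequency(self):
        for rf in (5.0, 6.0, 7.0):
            w = generate_pressure_waveform(WaveformParams(ring_freq=rf))
            pk = secondary_peak(dicrotic_ring_spectrum(w, 1.0, 32))
            assert pk.freq == pytest.approx(rf, abs=0.2)

    def test_no_ring_has_weaker_secondary_content(self, default_waveform):
        ringing = secondary_peak(dicrotic_ring_spectrum(default_waveform, 1.0, 32))
        flatw = generate_pressure_waveform(WaveformParams(ring_amp=0.0))
        s_flat = dicrotic_ring_spectrum(flatw, 1.0, 32)
        if s_flat is not None:
            pk = secondary_peak(s_flat)
            assert pk is None or pk.amp < ringing.amp
        # absence of a post-systolic dip is also an acceptable outcome
        assert ringing is not None

    def test_damped_measurement_suppresses_ring(self, default_waveform):
        """A bubble-degraded measurement attenuates the 5.4 Hz mode, the
        mechanism that removes the dicrotic notch from catheter traces."""
        clean_pk = secondary_peak(dicrotic_ring_spectrum(default_waveform, 1.0, 32))
        damped = steady_filtered(default_waveform, 3.0, 1.5)
        s = dicrotic_ring_spectrum(damped, 1.0, 32)
        damped_amp = 0.0 if s is None else (
            (secondary_peak(s) or (0, 0))[1])
        assert damped_amp < clean_pk.amp


class TestCurvature:
    def test_straight_ramp_has_zero_curvature(self):
        w = PressureWaveform(np.linspace(0.0, 100.0, 200), 100.0)
        qc = curvature_sum(w)
        assert qc.curvature_sum == pytest.approx(0.0, abs=1e-9)
        assert qc.distorted  # below threshold by construction

    def test_clean_default_waveform_passes_qc(self, default_waveform):
        qc = curvature_sum(default_waveform, 1.0)
        assert qc.curvature_sum > 3.85
        assert not qc.distorted

    def test_lowpass_strictly_reduces_curvature(self, default_waveform):
        blurred = steady_filtered(default_waveform, 2.0, 2.0)
        assert (curvature_sum(blurred, 1.0).curvature_sum
                < curvature_sum(default_waveform, 1.0).curvature_sum)

    def test_constant_cycle_is_degenerate(self):
        w = PressureWaveform(np.full(200, 7.0), 100.0)
        with pytest.raises(DegenerateSignalError):
            curvature_sum(w, 1.0)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    def test_affine_amplitude_invariance(self, default_waveform, scale, offset):
        """Unit-square normalization makes the statistic invariant under
        affine rescaling of the pressure axis."""
        w2 = default_waveform.with_samples(
            scale * default_waveform.samples + offset)
        a = curvature_sum(default_waveform, 1.0).curvature_sum
        b = curvature_sum(w2, 1.0).curvature_sum
        assert b == pytest.approx(a, rel=1e-9)
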