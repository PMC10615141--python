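"""Exact-frequency Fourier machinery: coefficients, sliding windows, fixed phase."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssvepdyn.epochs_io import TrialWaveform
from ssvepdyn.spectral import (fourier_coefficient, coherent_average,
                               sliding_timecourse, fixed_phase_timecourse,
                               estimate_phase, full_trial_spectrum, spline_smooth,
                               trial_coefficients)
from ssvepdyn.metrics import SuppressionTimeCourse, window_effect_size
from ssvepdyn.synthetic import generate_trial, ParticipantParams, suppression_weight, weight_for_db

from conftest import noise_free_config

FS = 1000.0


def sinusoid(amp, f, phase=0.0, duration=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * f * t + phase)


class TestFourierCoefficient:
    @pytest.mark.parametrize("amp,f,probe,expected", [
        (2.0, 5.0, 5.0, 2.0),      # on-bin orthogonality
        (0.0, 5.0, 5.0, 0.0),      # silence
    ])
    def test_on_bin_modulus(self, amp, f, probe, expected):
        c = fourier_coefficient(sinusoid(amp, f), probe, FS)
        assert abs(c) == pytest.approx(expected, abs=1e-12)

    def test_two_component_bin_separation(self):
        seg = sinusoid(2.0, 5.0) + sinusoid(1.0, 7.0, phase=1.1)
        assert abs(fourier_coefficient(seg, 7.0, FS)) == pytest.approx(1.0, abs=1e-12)
        assert abs(fourier_coefficient(seg, 5.0, FS)) == pytest.approx(2.0, abs=1e-12)

    def test_nyquist_and_short_segment_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fourier_coefficient(sinusoid(1, 5), 500.0, FS)
        with pytest.raises(ValueError):
            fourier_coefficient(np.array([1.0]), 5.0, FS)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(start=st.floats(0.0, 3.0), amp=st.floats(0.1, 10.0),
           phase=st.floats(0.0, 2 * np.pi))
    def test_modulus_invariant_to_window_start(self, start, amp, phase):
        # a pure on-bin sinusoid has the same modulus wherever the 1-s window sits
        t = np.arange(int(5 * FS)) / FS
        s = amp * np.sin(2 * np.pi * 7.0 * t + phase)
        i0 = int(round(start * FS))
        c = fourier_coefficient(s[i0:i0 + 1000], 7.0, FS)
        assert abs(c) == pytest.approx(amp, rel=1e-9)


class TestCoherentAverage:
    def test_identity_and_cancellation(self):
        w = TrialWaveform(sinusoid(1, 5), 0.0, FS)
        avg = coherent_average([w, w, w])
        np.testing.assert_allclose(avg.samples, w.samples)
        w_neg = TrialWaveform(-w.samples, 0.0, FS)
        np.testing.assert_allclose(coherent_average([w, w_neg]).samples, 0.0)

    def test_noise_attenuation_follows_sqrt_k(self, rng):
        base = sinusoid(1, 5)
        trials = [TrialWaveform(base + rng.standard_normal(base.size), 0.0, FS)
                  for _ in range(100)]
        resid = coherent_average(trials).samples - base
        assert resid.std() == pytest.approx(0.1, rel=0.15)

    def test_empty_and_ragged_rejected(self):
        with pytest.raises(ValueError):
            coherent_average([])
        with pytest.raises(ValueError, match="unequal"):
            coherent_average([TrialWaveform(np.zeros(10), 0.0, FS),
                              TrialWaveform(np.zeros(11), 0.0, FS)])


class TestSlidingTimecourse:
    def test_flat_course_for_constant_sinusoid(self):
        w = TrialWaveform(sinusoid(3.0, 5.0, duration=4.0), -1.0, FS)
        tc = sliding_timecourse(w, 5.0)
        np.testing.assert_allclose(tc.amplitudes, 3.0, atol=1e-9)
        assert np.all(np.diff(tc.times) > 0)

    def test_amplitude_step_blurred_to_midpoint_mean(self):
        # in-phase step a -> b at t0: the window centered on t0 averages to (a+b)/2,
        # and windows that clear the step recover a and b exactly
        a, b, t0 = 2.0, 3.0, 1.0
        t = np.arange(int(4 * FS)) / FS - 1.0
        s = np.where(t < t0, a, b) * np.sin(2 * np.pi * 5 * t)
        tc = sliding_timecourse(TrialWaveform(s, -1.0, FS), 5.0)
        at = lambda tt: tc.amplitudes[np.argmin(np.abs(tc.times - tt))]
        assert at(t0) == pytest.approx((a + b) / 2, abs=1e-9)
        assert at(t0 - 0.5) == pytest.approx(a, abs=1e-9)
        assert at(t0 + 0.5) == pytest.approx(b, abs=1e-9)

    def test_window_longer_than_epoch_rejected(self):
        w = TrialWaveform(sinusoid(1, 5, duration=0.5), 0.0, FS)
        with pytest.raises(ValueError, match="window"):
            sliding_timecourse(w, 5.0, window_s=1.0)

    def test_off_bin_frequency_warns(self):
        w = TrialWaveform(sinusoid(1, 5, duration=3.0), 0.0, FS)
        with pytest.warns(UserWarning, match="leakage"):
            sliding_timecourse(w, 5.5, window_s=1.0)


class TestFixedPhase:
    def test_matched_phase_equals_modulus_course(self):
        w = TrialWaveform(sinusoid(2.5, 7.0, phase=0.9, duration=4.0), -1.0, FS)
        mod = sliding_timecourse(w, 7.0)
        fp = fixed_phase_timecourse(w, 7.0, phase=0.9)
        np.testing.assert_allclose(fp.amplitudes, mod.amplitudes, atol=1e-9)

    def test_quadrature_phase_projects_to_zero(self):
        w = TrialWaveform(sinusoid(2.5, 7.0, phase=0.9, duration=4.0), -1.0, FS)
        fp = fixed_phase_timecourse(w, 7.0, phase=0.9 + np.pi / 2)
        np.testing.assert_allclose(fp.amplitudes, 0.0, atol=1e-9)

    def test_phase_estimated_from_full_trial_matches_modulus(self, rng):
        phase = float(rng.uniform(0, 2 * np.pi))
        w = TrialWaveform(sinusoid(1.8, 5.0, phase=phase, duration=6.0), 0.0, FS)
        mod = sliding_timecourse(w, 5.0)
        fp = fixed_phase_timecourse(w, 5.0)     # phase fit from whole trial
        np.testing.assert_allclose(fp.amplitudes, mod.amplitudes, atol=1e-6)
        wrapped = (estimate_phase(w, 5.0, (0.0, 6.0)) - phase + np.pi) % (2 * np.pi) - np.pi
        assert wrapped == pytest.approx(0.0, abs=1e-9)


class TestFullTrialSpectrum:
    def test_plaid_simulation_peaks_at_tagged_frequencies_only(self):
        w_static = weight_for_db(1.5)
        cfg = noise_free_config(transient_amplitude=0.0, w0=w_static,
                                w_inf_mon=w_static, w_inf_dich=w_static)
        params = ParticipantParams("P0", 3.0, 0.4, 1.2)
        trial = generate_trial(cfg, "plaid_mon", params, np.random.default_rng(0))
        w = TrialWaveform(trial[0], -cfg.epoch_pre, cfg.sample_rate)
        freqs, spec = full_trial_spectrum(w, interval=(0.0, cfg.trial_duration))
        hot = set(np.round(freqs[spec > 1e-9], 6))
        assert hot == {5.0, 7.0, 10.0, 12.0, 14.0}

    def test_fundamental_peak_equals_amplitude_times_mean_gain(self):
        cfg = noise_free_config(transient_amplitude=0.0, im_gain=0.0,
                                harmonic_gain=0.0)
        params = ParticipantParams("P0", 4.0, 0.0, 0.5)
        trial = generate_trial(cfg, "plaid_mon", params, np.random.default_rng(0))
        w = TrialWaveform(trial[0], -cfg.epoch_pre, cfg.sample_rate)
        freqs, spec = full_trial_spectrum(w, interval=(0.0, cfg.trial_duration))
        ts = np.arange(int(cfg.trial_duration * cfg.sample_rate)) / cfg.sample_rate
        gain = 1.0 / (1.0 + suppression_weight(ts, *cfg.weight_params("monocular")))
        expected = 4.0 * gain.mean()
        peak = spec[np.argmin(np.abs(freqs - 5.0))]
        assert peak == pytest.approx(expected, rel=1e-3)


class TestSplineSmooth:
    def grid_course(self, values):
        x = np.arange(0, 2, 0.01)
        return SuppressionTimeCourse(times=x, ratio_db=values(x), frequency=5.0,
                                     mask_type="monocular")

    def test_smooth_series_returned_close(self):
        tc = self.grid_course(lambda x: 0.5 * x**2 - x + 0.3)
        sm = spline_smooth(tc)
        assert sm.smoothed
        np.testing.assert_allclose(sm.ratio_db, tc.ratio_db, atol=1e-2)

    def test_constant_series_unchanged(self):
        tc = self.grid_course(lambda x: np.full_like(x, 1.7))
        np.testing.assert_allclose(spline_smooth(tc).ratio_db, 1.7, atol=1e-9)

    def test_statistics_reject_smoothed_courses(self):
        tc = self.grid_course(lambda x: x)
        sm = spline_smooth(tc)
        with pytest.raises(ValueError, match="display-only"):
            window_effect_size([sm, sm], early=(0.0, 0.5), late=(1.0, 1.5))

    def test_too_few_points_rejected(self):
        tc = SuppressionTimeCourse(times=np.arange(3.0), ratio_db=np.zeros(3),
                                   frequency=5.0, mask_type="monocular")
        with pytest.raises(ValueError, match="4 points"):
            spline_smooth(tc)


def test_trial_coefficients_match_direct_projection():
    w = TrialWaveform(sinusoid(2.0, 5.0, duration=3.0), 0.0, FS,
                      condition="alone_f1")
    cset = trial_coefficients([w, w], [5.0, 7.0], interval=(0.0, 3.0))
    assert cset.amplitudes[0, 0] == pytest.approx(2.0, abs=1e-12)
    assert cset.amplitudes[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert cset.window == (0.0, 3.0)
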