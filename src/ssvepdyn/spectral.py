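"""Exact-frequency Fourier analysis of frequency-tagged waveforms.

The tagged responses live at known integer frequencies, so instead of a full FFT the
pipeline projects each analysis segment onto a complex exponential at exactly the
frequency of interest, normalized so the modulus of the coefficient equals the
amplitude of a sinusoid at that frequency:

    c = (2/N) * sum_n s[n] * exp(-i 2 pi f n / fs)

When ``f * segment_duration`` is an integer the projection is orthogonal to every
other on-bin component, so a 1-s window gives leakage-free amplitude estimates at 5
and 7 Hz (and their harmonics and the 12 Hz intermodulation term).  Sliding the 1-s
window across the coherently averaged trial yields amplitude-vs-time courses; a
fixed-phase variant projects onto a real sinusoid of known phase instead of taking
the modulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .epochs_io import TrialWaveform

__all__ = [
    "ComplexCoefficientSet",
    "AmplitudeTimeCourse",
    "fourier_coefficient",
    "coherent_average",
    "trial_coefficients",
    "sliding_timecourse",
    "fixed_phase_timecourse",
    "estimate_phase",
    "full_trial_spectrum",
    "spline_smooth",
]


def fourier_coefficient(segment: np.ndarray, f: float, sample_rate: float) -> complex:
    """Complex Fourier coefficient of a segment at one frequency.

    Normalized by 2/N so that for a sinusoid ``A*sin(2*pi*f*t + phi)`` whose frequency
    is an exact bin of the segment (``f * duration`` integer) the modulus equals A.
    The phase reference is the start of the segment.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("segment must hold at least 2 samples")
    if f >= sample_rate / 2:
        raise ValueError(f"frequency {f} Hz is at or above Nyquist ({sample_rate / 2} Hz)")
    n = np.arange(segment.size)
    return complex((2.0 / segment.size)
                   * np.sum(segment * np.exp(-2j * np.pi * f * n / sample_rate)))


def coherent_average(trials: list[TrialWaveform]) -> TrialWaveform:
    """Pointwise mean across trials (phase-locked averaging).

    Preserves components with a consistent phase across trials and attenuates
    non-phase-locked noise by ~1/sqrt(K).
    """
    if not trials:
        raise ValueError("need at least one trial to average")
    lengths = {t.samples.size for t in trials}
    if len(lengths) != 1:
        raise ValueError(f"trials have unequal lengths: {sorted(lengths)}")
    stack = np.stack([t.samples for t in trials])
    first = trials[0]
    return TrialWaveform(samples=stack.mean(axis=0), time_zero=first.time_zero,
                         sample_rate=first.sample_rate, condition=first.condition,
                         participant_id=first.participant_id)


@dataclass
class ComplexCoefficientSet:
    """Per-trial complex Fourier coefficients at the tagged frequencies.

    ``coefficients`` has shape (n_trials, n_frequencies); ``window`` records the
    (start_s, length_s) analysis segment the coefficients were computed over,
    in onset-relative time.
    """

    coefficients: np.ndarray
    frequencies: np.ndarray
    conditions: list[str]
    window: tuple[float, float]
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be trials x frequencies")
        if self.coefficients.shape[1] != self.frequencies.size:
            raise ValueError("coefficient columns must match frequencies")
        if len(self.conditions) != self.coefficients.shape[0]:
            raise ValueError("conditions must match trial count")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients contain non-finite values")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def column(self, frequency: float) -> np.ndarray:
        match = np.nonzero(np.isclose(self.frequencies, frequency))[0]
        if match.size == 0:
            raise KeyError(f"no coefficients at {frequency} Hz")
        return self.coefficients[:, match[0]]


def trial_coefficients(trials: list[TrialWaveform], frequencies,
                       interval: tuple[float, float] | None = None
                       ) -> ComplexCoefficientSet:
    """Full-stimulation-period coefficients per trial at each analysis frequency.

    ``interval`` is (start_s, end_s) relative to onset; default (0, end-of-epoch
    relative to the waveform) should normally be the stimulation period supplied by
    the caller.
    """
    if not trials:
        raise ValueError("no trials supplied")
    first = trials[0]
    fs = first.sample_rate
    if interval is None:
        interval = (0.0, first.time_zero + first.duration)
    start_idx = int(round((interval[0] - first.time_zero) * fs))
    stop_idx = int(round((interval[1] - first.time_zero) * fs))
    if not (0 <= start_idx < stop_idx <= first.samples.size):
        raise ValueError(f"analysis interval {interval} outside epoch")
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    n = np.arange(stop_idx - start_idx)
    basis = np.exp(-2j * np.pi * frequencies[:, None] * n[None, :] / fs)
    stack = np.stack([t.samples[start_idx:stop_idx] for t in trials])
    coeffs = (2.0 / n.size) * stack @ basis.T
    return ComplexCoefficientSet(
        coefficients=coeffs, frequencies=frequencies,
        conditions=[t.condition for t in trials], window=(interval[0], interval[1] - interval[0]),
        participant_id=first.participant_id)


@dataclass
class AmplitudeTimeCourse:
    """Amplitude (uV) versus sliding-window center time at one frequency."""

    times: np.ndarray              # s relative to onset, strictly increasing
    amplitudes: np.ndarray         # uV, >= 0 (signed for fixed-phase projections)
    frequency: float
    condition: str | None = None
    participant_id: str | None = None
    window_s: float = 1.0
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must align")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes contain non-finite values")


def _window_grid(avg: TrialWaveform, window_s: float, step_s: float):
    """Window-center times on the step grid, with start indices, fully inside the epoch."""
    fs = avg.sample_rate
    win_len = int(round(window_s * fs))
    if win_len > avg.samples.size:
        raise ValueError("window longer than epoch")
    if win_len < 2:
        raise ValueError("window must hold at least 2 samples")
    t_start = avg.time_zero
    t_end = avg.time_zero + avg.samples.size / fs
    k_min = int(np.ceil(round((t_start + window_s / 2) / step_s, 9)))
    k_max = int(np.floor(round((t_end - window_s / 2) / step_s, 9)))
    centers, starts = [], []
    for k in range(k_min, k_max + 1):
        t_c = k * step_s
        i0 = int(round((t_c - window_s / 2 - avg.time_zero) * fs))
        if 0 <= i0 and i0 + win_len <= avg.samples.size:
            centers.append(t_c)
            starts.append(i0)
    return np.asarray(centers), np.asarray(starts, dtype=int), win_len


def sliding_timecourse(avg: TrialWaveform, f: float, window_s: float = 1.0,
                       step_s: float = 0.01) -> AmplitudeTimeCourse:
    """Sliding-window Fourier amplitude time course.

    For each center time on the step grid (centers are multiples of ``step_s`` in
    onset-relative time), the modulus of the exact-frequency Fourier coefficient over
    the half-open window ``[t_c - window_s/2, t_c + window_s/2)``.  Windows that would
    extend past the epoch are dropped, not padded.
    """
    if f >= avg.sample_rate / 2:
        raise ValueError("frequency at or above Nyquist")
    if abs(f * window_s - round(f * window_s)) > 1e-9:
        warnings.warn(
            f"{f} Hz is not an exact bin of a {window_s}-s window; amplitude "
            "estimates will suffer spectral leakage", stacklevel=2)
    centers, starts, win_len = _window_grid(avg, window_s, step_s)
    fs = avg.sample_rate
    n = np.arange(avg.samples.size)
    demod = avg.samples * np.exp(-2j * np.pi * f * n / fs)
    csum = np.concatenate([[0.0 + 0.0j], np.cumsum(demod)])
    sums = csum[starts + win_len] - csum[starts]
    amps = (2.0 / win_len) * np.abs(sums)
    return AmplitudeTimeCourse(times=centers, amplitudes=amps, frequency=f,
                               condition=avg.condition,
                               participant_id=avg.participant_id, window_s=window_s)


def estimate_phase(avg: TrialWaveform, f: float,
                   interval: tuple[float, float]) -> float:
    """Phase (rad) of ``A*sin(2*pi*f*t + phi)`` fitted over an onset-relative interval.

    The phase is referenced to onset-relative time t so it can be reused across
    windows anywhere in the epoch.
    """
    fs = avg.sample_rate
    start_idx = int(round((interval[0] - avg.time_zero) * fs))
    stop_idx = int(round((interval[1] - avg.time_zero) * fs))
    seg = avg.samples[start_idx:stop_idx]
    t = avg.time_zero + np.arange(avg.samples.size)[start_idx:stop_idx] / fs
    c = (2.0 / seg.size) * np.sum(seg * np.exp(-2j * np.pi * f * t))
    # s = A sin(wt + phi) = A cos(wt + phi - pi/2)  ->  c = A exp(i(phi - pi/2))
    return float(np.angle(c) + np.pi / 2)


def fixed_phase_timecourse(avg: TrialWaveform, f: float, phase: float | None = None,
                           window_s: float = 1.0, step_s: float = 0.01,
                           phase_interval: tuple[float, float] | None = None
                           ) -> AmplitudeTimeCourse:
    """Amplitude time course by projection onto a sine of fixed frequency and phase.

    Each window's value is ``(2/N) * sum s[n] * sin(2*pi*f*t[n] + phase)`` with t in
    onset-relative seconds.  With ``phase=None`` the phase is estimated once from the
    whole-trial coefficient over ``phase_interval`` (default: the full epoch).  For a
    phase-locked signal this equals the modulus-based course; a quadrature phase error
    drives the projection to zero.  Values may be negative for anti-phase signals.
    """
    if phase is None:
        if phase_interval is None:
            phase_interval = (avg.time_zero, avg.time_zero + avg.duration)
        phase = estimate_phase(avg, f, phase_interval)
    centers, starts, win_len = _window_grid(avg, window_s, step_s)
    fs = avg.sample_rate
    t = avg.time_zero + np.arange(avg.samples.size) / fs
    proj = avg.samples * np.sin(2 * np.pi * f * t + phase)
    csum = np.concatenate([[0.0], np.cumsum(proj)])
    sums = csum[starts + win_len] - csum[starts]
    amps = (2.0 / win_len) * sums
    return AmplitudeTimeCourse(times=centers, amplitudes=amps, frequency=f,
                               condition=avg.condition,
                               participant_id=avg.participant_id, window_s=window_s)


def full_trial_spectrum(avg: TrialWaveform,
                        interval: tuple[float, float] | None = None,
                        fmax: float | None = None):
    """Amplitude spectrum of the analyzed segment on its natural DFT grid.

    Returns ``(frequencies, amplitudes)`` with 2/N normalization (so an on-bin
    sinusoid of amplitude A shows a peak of height A) and resolution ``1/duration``.
    ``interval`` defaults to the full epoch; pass the stimulation period to match the
    tagged-response peaks.
    """
    fs = avg.sample_rate
    if interval is None:
        seg = avg.samples
    else:
        start_idx = int(round((interval[0] - avg.time_zero) * fs))
        stop_idx = int(round((interval[1] - avg.time_zero) * fs))
        if not (0 <= start_idx < stop_idx <= avg.samples.size):
            raise ValueError(f"interval {interval} outside epoch")
        seg = avg.samples[start_idx:stop_idx]
    spec = np.abs(np.fft.rfft(seg)) * 2.0 / seg.size
    spec[0] /= 2.0
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / fs)
    if fmax is not None:
        keep = freqs <= fmax
        freqs, spec = freqs[keep], spec[keep]
    return freqs, spec


def spline_smooth(tc, lam: float | None = None):
    """Cubic smoothing-spline fit of a time course, for display only.

    Returns a copy evaluated on the input grid with ``smoothed=True``; statistical
    operations reject smoothed inputs.  Works on amplitude and suppression time
    courses alike (any object with ``times`` and an amplitude/ratio array).
    """
    if tc.times.size < 4:
        raise ValueError("need at least 4 points for a cubic smoothing spline")
    values = tc.amplitudes if hasattr(tc, "amplitudes") else tc.ratio_db
    spline = make_smoothing_spline(tc.times, values, lam=lam)
    smooth = spline(tc.times)
    if hasattr(tc, "amplitudes"):
        return replace(tc, amplitudes=np.maximum(smooth, 0.0), smoothed=True)
    return replace(tc, ratio_db=smooth, smoothed=True)


def timecourses_frame(courses: list[AmplitudeTimeCourse]) -> pd.DataFrame:
    """Tidy frame: participant, condition, frequency_hz, time_s, amplitude_uv."""
    parts = [pd.DataFrame({
        "participant": c.participant_id,
        "condition": c.condition,
        "frequency_hz": c.frequency,
        "time_s": c.times,
        "amplitude_uv": c.amplitudes,
    }) for c in courses]
    return pd.concat(parts, ignore_index=True)
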