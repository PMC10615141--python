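"""Suppression ratios, pooling, windowed effect sizes, and intermodulation indices.

The suppression ratio divides the target-only amplitude time course by the
target+mask time course and converts to dB:

    ratio_db(t) = 20 * log10( max(A_alone(t), floor) / max(A_masked(t), floor) )

Positive dB means the mask suppressed the tagged response; an amplitude floor keeps
the ratio finite on noise-free simulations.  Because the sliding window blurs both
the numerator and the denominator identically, multiplicative distortions common to
the two conditions (onset transients, window smearing, broadband intertrial noise)
largely cancel in the ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import AmplitudeTimeCourse

__all__ = [
    "DEFAULT_FLOOR_UV",
    "SuppressionTimeCourse",
    "EffectSizeResult",
    "IntermodulationTimeCourse",
    "suppression_ratio",
    "pool_timecourses",
    "window_effect_size",
    "intermodulation_timecourse",
    "suppression_frame",
]

#: Default amplitude floor (uV) applied before the ratio.
DEFAULT_FLOOR_UV = 1e-3


@dataclass
class SuppressionTimeCourse:
    """dB suppression (alone vs masked) versus window-center time."""

    times: np.ndarray
    ratio_db: np.ndarray
    frequency: float | None        # None for pooled courses
    mask_type: str | None          # 'monocular', 'dichoptic', or 'pooled'
    participant_id: str | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio_db = np.asarray(self.ratio_db, dtype=float)
        if self.times.size != self.ratio_db.size:
            raise ValueError("times and ratio_db must align")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.ratio_db)):
            raise ValueError("ratio_db contains non-finite values")

    @property
    def ratio(self) -> np.ndarray:
        """Raw amplitude ratio (alone/masked), the linear-scale counterpart."""
        return 10.0 ** (self.ratio_db / 20.0)

    def restrict(self, t_min: float, t_max: float) -> "SuppressionTimeCourse":
        """Copy restricted to centers in [t_min, t_max]."""
        keep = (self.times >= t_min - 1e-12) & (self.times <= t_max + 1e-12)
        return SuppressionTimeCourse(self.times[keep], self.ratio_db[keep],
                                     self.frequency, self.mask_type,
                                     self.participant_id, self.smoothed)


@dataclass
class EffectSizeResult:
    """Paired effect size comparing late-window to early-window suppression."""

    window_early: tuple[float, float]
    window_late: tuple[float, float]
    participant_means_early: np.ndarray
    participant_means_late: np.ndarray
    cohen_d: float
    flavor: str = "paired"
    degenerate: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "window_early_s": list(self.window_early),
            "window_late_s": list(self.window_late),
            "participant_means_early_db": self.participant_means_early.tolist(),
            "participant_means_late_db": self.participant_means_late.tolist(),
            "cohen_d": self.cohen_d,
            "flavor": self.flavor,
            "degenerate": self.degenerate,
        }, indent=2))


@dataclass
class IntermodulationTimeCourse:
    """Proportional increase of the f1+f2 response relative to the alone baseline."""

    times: np.ndarray
    index: np.ndarray              # dimensionless, >= -1
    frequency: float
    participant_id: str | None = None
    mask_type: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        if np.any(self.index < -1.0 - 1e-12):
            raise ValueError("intermodulation index below -1")


def _check_grids(a: AmplitudeTimeCourse, b: AmplitudeTimeCourse) -> None:
    if a.times.size != b.times.size or not np.allclose(a.times, b.times):
        raise ValueError("time grids differ between the two courses")


def _reject_smoothed(*courses) -> None:
    if any(getattr(c, "smoothed", False) for c in courses):
        raise ValueError("smoothed time courses are display-only; "
                         "statistical operations require unsmoothed data")


def suppression_ratio(tc_alone: AmplitudeTimeCourse, tc_masked: AmplitudeTimeCourse,
                      floor: float = DEFAULT_FLOOR_UV,
                      mask_type: str | None = None) -> SuppressionTimeCourse:
    """dB ratio of the alone course to the masked course on a shared time grid."""
    _check_grids(tc_alone, tc_masked)
    if not np.isclose(tc_alone.frequency, tc_masked.frequency):
        raise ValueError("courses are at different frequencies")
    num = np.maximum(tc_alone.amplitudes, floor)
    den = np.maximum(tc_masked.amplitudes, floor)
    # difference of logs keeps suppression_ratio(a, b) == -suppression_ratio(b, a)
    # exact in floating point
    db = 20.0 * (np.log10(num) - np.log10(den))
    return SuppressionTimeCourse(
        times=tc_alone.times.copy(), ratio_db=db, frequency=tc_alone.frequency,
        mask_type=mask_type, participant_id=tc_alone.participant_id,
        smoothed=tc_alone.smoothed or tc_masked.smoothed)


def pool_timecourses(courses: list[SuppressionTimeCourse],
                     label: str = "pooled") -> SuppressionTimeCourse:
    """Arithmetic mean of dB values across courses (e.g. over frequency and mask type).

    All courses must share a time grid and belong to one participant.
    """
    if not courses:
        raise ValueError("nothing to pool")
    times = courses[0].times
    for c in courses[1:]:
        if c.times.size != times.size or not np.allclose(c.times, times):
            raise ValueError("pooled courses must share a time grid")
    db = np.mean([c.ratio_db for c in courses], axis=0)
    freqs = {c.frequency for c in courses}
    masks = {c.mask_type for c in courses}
    return SuppressionTimeCourse(
        times=times.copy(), ratio_db=db,
        frequency=freqs.pop() if len(freqs) == 1 else None,
        mask_type=masks.pop() if len(masks) == 1 else label,
        participant_id=courses[0].participant_id,
        smoothed=any(c.smoothed for c in courses))


def _window_mean(course: SuppressionTimeCourse, window: tuple[float, float]) -> float:
    lo, hi = window
    sel = (course.times >= lo - 1e-12) & (course.times < hi - 1e-12)
    if not sel.any():
        raise ValueError(f"no window centers inside {window}")
    return float(course.ratio_db[sel].mean())


def window_effect_size(courses: list[SuppressionTimeCourse],
                       early: tuple[float, float] = (0.0, 1.0),
                       late: tuple[float, float] = (3.0, 4.0),
                       flavor: str = "paired") -> EffectSizeResult:
    """Cohen's d for the growth of suppression from an early to a late window.

    Per participant, the mean dB ratio over window centers in each interval
    (half-open, onset-relative seconds); the effect size of the late-minus-early
    difference across participants.  ``flavor='paired'`` (default) divides by the SD
    of the differences; ``flavor='pooled'`` divides by the pooled SD of the two sets
    of window means.
    """
    _reject_smoothed(*courses)
    if len(courses) < 2:
        raise ValueError("need at least 2 participants")
    if not (early[1] <= late[0] or late[1] <= early[0]):
        raise ValueError("effect-size windows must not overlap")
    e = np.array([_window_mean(c, early) for c in courses])
    l = np.array([_window_mean(c, late) for c in courses])
    diff = l - e
    degenerate = False
    if flavor == "paired":
        sd = diff.std(ddof=1)
    elif flavor == "pooled":
        sd = np.sqrt((e.var(ddof=1) + l.var(ddof=1)) / 2.0)
    else:
        raise ValueError(f"unknown effect-size flavor {flavor!r}")
    if sd == 0.0:
        degenerate = True
        d = 0.0 if diff.mean() == 0 else float(np.sign(diff.mean()) * np.inf)
    else:
        d = float(diff.mean() / sd)
    return EffectSizeResult(window_early=early, window_late=late,
                            participant_means_early=e, participant_means_late=l,
                            cohen_d=d, flavor=flavor, degenerate=degenerate)


def intermodulation_timecourse(tc_plaid_im: AmplitudeTimeCourse,
                               alone_baselines: list[AmplitudeTimeCourse],
                               floor: float = DEFAULT_FLOOR_UV
                               ) -> IntermodulationTimeCourse:
    """Proportional increase of the plaid's f1+f2 amplitude over the alone baseline.

    The baseline is the mean of the alone-condition courses at the intermodulation
    frequency (where no true intermodulation response exists, so the baseline is the
    noise floor):

        index(t) = (A_plaid(t) - A_base(t)) / max(A_base(t), floor)
    """
    if not alone_baselines:
        raise ValueError("need at least one alone-condition baseline course")
    for b in alone_baselines:
        _check_grids(tc_plaid_im, b)
    base = np.mean([b.amplitudes for b in alone_baselines], axis=0)
    denom = np.maximum(base, floor)
    idx = (tc_plaid_im.amplitudes - base) / denom
    return IntermodulationTimeCourse(times=tc_plaid_im.times.copy(), index=idx,
                                     frequency=tc_plaid_im.frequency,
                                     participant_id=tc_plaid_im.participant_id)


def suppression_frame(courses: list[SuppressionTimeCourse]) -> pd.DataFrame:
    """Tidy frame: participant, frequency_hz, mask_type, time_s, ratio, ratio_db."""
    parts = [pd.DataFrame({
        "participant": c.participant_id,
        "frequency_hz": float("nan") if c.frequency is None else float(c.frequency),
        "mask_type": c.mask_type,
        "time_s": c.times,
        "ratio": c.ratio,
        "ratio_db": c.ratio_db,
    }) for c in courses]
    return pd.concat(parts, ignore_index=True)
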