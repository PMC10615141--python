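"""Trial-level quality control: Mahalanobis outlier rejection in the complex plane.

Each trial's Fourier coefficient at a tagged frequency is a point in the complex
plane; artifact trials land far from the condition's cloud.  A trial is excluded when
the Mahalanobis distance of its (real, imag) pair from the condition's sample mean —
under the condition's sample covariance — exceeds a threshold (3 by default).  Under
a clean bivariate-Gaussian null the squared distance is chi-square with 2 df, so the
expected exclusion fraction at threshold 3 is P(chi2_2 > 9) = exp(-4.5) ~ 1.11%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs_io import TrialWaveform
from .spectral import ComplexCoefficientSet

__all__ = ["OutlierReport", "complex_mahalanobis", "reject_outliers"]


@dataclass
class OutlierReport:
    """Per-trial distances and exclusion decisions, plus per-condition fractions."""

    distances: np.ndarray          # trials x frequencies (or trials x 1 if joint)
    frequencies: np.ndarray
    excluded: np.ndarray           # boolean per trial
    conditions: list[str]
    threshold: float
    joint: bool = False

    @property
    def exclusion_fraction(self) -> float:
        return float(np.mean(self.excluded))

    def condition_fractions(self) -> dict[str, float]:
        labels = np.asarray(self.conditions)
        return {c: float(np.mean(self.excluded[labels == c]))
                for c in dict.fromkeys(self.conditions)}

    def to_frame(self) -> pd.DataFrame:
        cols = {"trial": np.arange(self.excluded.size),
                "condition": self.conditions,
                "excluded": self.excluded}
        if self.joint:
            cols["distance_joint"] = self.distances[:, 0]
        else:
            for j, f in enumerate(self.frequencies):
                cols[f"distance_{f:g}hz"] = self.distances[:, j]
        return pd.DataFrame(cols)

    def to_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "joint": self.joint,
            "frequencies_hz": [float(f) for f in self.frequencies],
            "exclusion_fraction": self.exclusion_fraction,
            "condition_fractions": self.condition_fractions(),
            "excluded_trials": [int(i) for i in np.nonzero(self.excluded)[0]],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _mahalanobis_2d(points: np.ndarray) -> np.ndarray:
    """Mahalanobis distances of rows from their own sample mean/covariance.

    ``points`` is (n, d) real.  A singular covariance is ridge-regularized with a
    warning; the degenerate all-identical case yields all-zero distances.
    """
    n, d = points.shape
    if n < 3:
        raise ValueError("need at least 3 trials to estimate a covariance")
    mu = points.mean(axis=0)
    centered = points - mu
    cov = centered.T @ centered / (n - 1)
    scale = np.trace(cov) / d
    if scale == 0.0:
        # all points identical: distances are all zero by convention
        warnings.warn("zero covariance in Mahalanobis QC; distances set to 0",
                      stacklevel=3)
        return np.zeros(n)
    # regularize if ill-conditioned
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular covariance in Mahalanobis QC; ridge-regularized",
                      stacklevel=3)
        cov = cov + 1e-9 * scale * np.eye(d)
    sol = np.linalg.solve(cov, centered.T)
    d2 = np.einsum("ij,ji->i", centered, sol)
    return np.sqrt(np.maximum(d2, 0.0))


def complex_mahalanobis(coeffs: ComplexCoefficientSet, frequency: float,
                        conditions: np.ndarray | None = None) -> np.ndarray:
    """Per-trial Mahalanobis distance of the complex coefficient at one frequency.

    Each coefficient is treated as a (real, imag) 2-vector; mean and covariance are
    estimated within condition (trials of the same condition only), so a trial's
    distance never depends on other conditions' trials.
    """
    col = coeffs.column(frequency)
    points = np.column_stack([col.real, col.imag])
    labels = np.asarray(conditions if conditions is not None else coeffs.conditions)
    out = np.empty(points.shape[0])
    for c in dict.fromkeys(labels):
        sel = labels == c
        out[sel] = _mahalanobis_2d(points[sel])
    return out


def reject_outliers(trials: list[TrialWaveform], coeffs: ComplexCoefficientSet,
                    threshold: float = 3.0, joint: bool = False
                    ) -> tuple[list[TrialWaveform], OutlierReport]:
    """Exclude trials whose coefficient distance exceeds ``threshold``.

    Default (``joint=False``): a distance is computed per analysis frequency on the
    (real, imag) pair and a trial is excluded if it exceeds the threshold at ANY
    frequency.  With ``joint=True`` the real/imag pairs of all frequencies are stacked
    into one vector and a single distance is computed.  Retained trial order is
    preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = np.asarray(coeffs.conditions)
    n_trials = coeffs.coefficients.shape[0]
    if len(trials) != n_trials:
        raise ValueError("trials and coefficient set must align")

    if joint:
        stacked = np.hstack([
            np.column_stack([coeffs.coefficients[:, j].real,
                             coeffs.coefficients[:, j].imag])
            for j in range(coeffs.frequencies.size)])
        distances = np.empty((n_trials, 1))
        for c in dict.fromkeys(labels):
            sel = labels == c
            distances[sel, 0] = _mahalanobis_2d(stacked[sel])
    else:
        distances = np.column_stack([
            complex_mahalanobis(coeffs, f) for f in coeffs.frequencies])

    excluded = np.any(distances > threshold, axis=1)
    if excluded.all():
        raise ValueError("all trials excluded; downstream averages undefined")
    retained = [t for t, ex in zip(trials, excluded) if not ex]
    report = OutlierReport(distances=distances, frequencies=coeffs.frequencies,
                           excluded=excluded, conditions=list(labels),
                           threshold=threshold, joint=joint)
    return retained, report
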