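"""Cluster-corrected nonparametric inference on suppression time courses.

Two tests, both controlling the family-wise error over window centers with the
max-cluster permutation scheme:

* increasing-suppression trend test — at each center ``t_c``, a paired t test across
  participants of ``ratio_db(t_c + lag/2) - ratio_db(t_c - lag/2)`` (lag 1 s by
  default, one-sided for an increase).  Clusters are maximal runs of temporally
  adjacent supra-threshold centers, scored by their summed t.  The null flips the
  sign of each participant's whole difference series (the exchangeable null for a
  one-sample design with symmetric noise) and records the max cluster sum per
  permutation; a cluster is significant when its sum exceeds the 95th percentile of
  that null.

* two-group comparison — pointwise two-sample t between groups (two-sided by
  default); the null permutes group membership with group sizes preserved, scoring
  the max absolute cluster sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .metrics import SuppressionTimeCourse

__all__ = [
    "ClusterTestConfig",
    "Cluster",
    "ClusterTestResult",
    "trend_t_series",
    "find_clusters",
    "cluster_test_increase",
    "cluster_test_groups",
]


@dataclass
class ClusterTestConfig:
    """Knobs of the permutation tests; defaults mirror the analysis constants."""

    lag: float = 1.0                   # s, temporal separation of the trend contrast
    alpha_pointwise: float = 0.05      # cluster-forming threshold
    n_permutations: int = 1000
    sidedness: str = "one_sided_increase"   # or "two_sided"
    null_type: str = "sign_flip"            # or "label_shuffle"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_pointwise < 1.0:
            raise ValueError("alpha_pointwise must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.lag <= 0:
            raise ValueError("lag must be positive")
        if self.sidedness not in ("one_sided_increase", "two_sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.null_type not in ("sign_flip", "label_shuffle"):
            raise ValueError(f"unknown null_type {self.null_type!r}")


@dataclass
class Cluster:
    start_s: float
    end_s: float
    summed_t: float
    start_idx: int
    end_idx: int           # inclusive
    significant: bool = False
    p_value: float | None = None


@dataclass
class ClusterTestResult:
    times: np.ndarray                  # window centers the t series is defined on
    pointwise_t: np.ndarray
    df: int
    threshold: float
    clusters: list[Cluster]
    null_max: np.ndarray               # permutation max cluster statistic
    critical_value: float
    config: ClusterTestConfig

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    @property
    def significant_timepoints(self) -> np.ndarray:
        sel = np.zeros(self.times.size, dtype=bool)
        for c in self.significant_clusters:
            sel[c.start_idx:c.end_idx + 1] = True
        return self.times[sel]

    def last_significant_time(self) -> float | None:
        """End time (s) of the earliest significant cluster, if any."""
        sig = self.significant_clusters
        return min((c for c in sig), key=lambda c: c.start_s).end_s if sig else None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "df": self.df,
            "threshold": self.threshold,
            "critical_value": self.critical_value,
            "n_permutations": int(self.null_max.size),
            "clusters": [{
                "start_s": c.start_s, "end_s": c.end_s, "summed_t": c.summed_t,
                "significant": c.significant, "p_value": c.p_value,
            } for c in self.clusters],
            "significant_timepoints_s": self.significant_timepoints.tolist(),
            "null_max_quantiles": {
                q: float(np.quantile(self.null_max, float(q)))
                for q in ("0.5", "0.9", "0.95", "0.99")},
        }, indent=2, default=float))


def _reject_smoothed(courses) -> None:
    if any(c.smoothed for c in courses):
        raise ValueError("smoothed time courses are display-only; "
                         "statistical tests require unsmoothed data")


def _course_matrix(courses: list[SuppressionTimeCourse]) -> tuple[np.ndarray, np.ndarray]:
    times = courses[0].times
    for c in courses[1:]:
        if c.times.size != times.size or not np.allclose(c.times, times):
            raise ValueError("courses must share a time grid")
    return times, np.stack([c.ratio_db for c in courses])


def _lag_offset(times: np.ndarray, lag: float) -> int:
    """Lag expressed in grid steps, snapped to the nearest representable offset."""
    step = float(np.median(np.diff(times)))
    k = int(round(lag / step))
    if k < 1:
        raise ValueError("lag is below the time-grid resolution")
    if abs(k * step - lag) > 1e-9:
        import warnings
        warnings.warn(f"lag {lag} s is not a multiple of the {step} s step; "
                      f"snapped to {k * step:.6g} s", stacklevel=3)
    return k


def _lagged_differences(courses: list[SuppressionTimeCourse], lag: float):
    """Participant x center matrix of lagged differences, and the center times."""
    times, mat = _course_matrix(courses)
    k = _lag_offset(times, lag)
    half = k // 2
    # center t_c needs both t_c - lag/2 and t_c + lag/2 on the grid
    if k % 2 == 0:
        centers = times[half:times.size - half]
        diffs = mat[:, k:] - mat[:, :-k]
    else:
        # odd lag in steps: centers fall midway between grid points
        centers = (times[k:] + times[:-k]) / 2.0
        diffs = mat[:, k:] - mat[:, :-k]
    return centers, diffs


def _one_sample_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t across participants (rows) per column, with +/-inf sentinels for
    zero-variance columns (a nonzero constant difference is infinitely reliable)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    return t


def trend_t_series(courses: list[SuppressionTimeCourse], lag: float = 1.0):
    """Paired-t series for the increase in suppression across a fixed lag.

    Returns ``(center_times, t_values)``: for every center with both endpoints on the
    shared grid, the one-sample t (df = N-1) across participants of the difference
    ``ratio_db(t_c + lag/2) - ratio_db(t_c - lag/2)``.
    """
    _reject_smoothed(courses)
    if len(courses) < 3:
        raise ValueError("need at least 3 participants")
    centers, diffs = _lagged_differences(courses, lag)
    return centers, _one_sample_t(diffs)


def find_clusters(t_series: np.ndarray, df: int, alpha_pointwise: float = 0.05,
                  sidedness: str = "one_sided_increase",
                  times: np.ndarray | None = None) -> list[Cluster]:
    """Maximal runs of temporally adjacent supra-threshold t values.

    One-sided: points with ``t > t_{1-alpha, df}``; two-sided: ``|t| >
    t_{1-alpha/2, df}`` (runs are not split on sign changes; the summed t keeps its
    sign).  Returns clusters with their summed t.
    """
    t_series = np.asarray(t_series, dtype=float)
    if t_series.size == 0:
        raise ValueError("empty t series")
    if sidedness == "one_sided_increase":
        thresh = stats.t.ppf(1 - alpha_pointwise, df)
        supra = t_series > thresh
    else:
        thresh = stats.t.ppf(1 - alpha_pointwise / 2, df)
        supra = np.abs(t_series) > thresh
    if times is None:
        times = np.arange(t_series.size, dtype=float)
    clusters: list[Cluster] = []
    i = 0
    while i < supra.size:
        if supra[i]:
            j = i
            while j + 1 < supra.size and supra[j + 1]:
                j += 1
            clusters.append(Cluster(start_s=float(times[i]), end_s=float(times[j]),
                                    summed_t=float(t_series[i:j + 1].sum()),
                                    start_idx=i, end_idx=j))
            i = j + 1
        else:
            i += 1
    return clusters


def _max_cluster_stat(t_series: np.ndarray, supra: np.ndarray,
                      two_sided: bool) -> float:
    """Max cluster score of one t series given its supra-threshold mask."""
    if not supra.any():
        return 0.0
    edges = np.diff(supra.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if supra[0]:
        starts = np.concatenate([[0], starts])
    if supra[-1]:
        ends = np.concatenate([ends, [supra.size]])
    csum = np.concatenate([[0.0], np.cumsum(t_series)])
    sums = csum[ends] - csum[starts]
    return float(np.max(np.abs(sums) if two_sided else sums))


def _null_max_from_tmatrix(t_matrix: np.ndarray, thresh: float,
                           two_sided: bool) -> np.ndarray:
    """Max cluster statistic per row of a (permutations x centers) t matrix."""
    supra = np.abs(t_matrix) > thresh if two_sided else t_matrix > thresh
    out = np.empty(t_matrix.shape[0])
    for i in range(t_matrix.shape[0]):
        out[i] = _max_cluster_stat(t_matrix[i], supra[i], two_sided)
    return out


def _finalize(times, t_obs, df, thresh, clusters, null_max, two_sided,
              config) -> ClusterTestResult:
    critical = float(np.quantile(null_max, 0.95))
    n_perm = null_max.size
    for c in clusters:
        score = abs(c.summed_t) if two_sided else c.summed_t
        c.significant = bool(score > critical)
        c.p_value = float((1 + np.sum(null_max >= score)) / (n_perm + 1))
    return ClusterTestResult(times=times, pointwise_t=t_obs, df=df,
                             threshold=float(thresh), clusters=clusters,
                             null_max=null_max, critical_value=critical,
                             config=config)


def cluster_test_increase(courses: list[SuppressionTimeCourse],
                          config: ClusterTestConfig | None = None
                          ) -> ClusterTestResult:
    """Cluster-corrected test for suppression increasing over time.

    Observed clusters come from :func:`trend_t_series`; the null distribution flips
    the sign of each participant's lagged-difference series at random (participant-
    level sign flips), recomputing the maximum cluster sum each time.
    """
    config = config or ClusterTestConfig()
    if config.null_type != "sign_flip":
        raise ValueError("the trend test uses the sign_flip null")
    _reject_smoothed(courses)
    if len(courses) < 3:
        raise ValueError("need at least 3 participants")
    centers, diffs = _lagged_differences(courses, config.lag)
    n = diffs.shape[0]
    df = n - 1
    one_sided = config.sidedness == "one_sided_increase"
    thresh = stats.t.ppf(1 - (config.alpha_pointwise if one_sided
                              else config.alpha_pointwise / 2), df)

    t_obs = _one_sample_t(diffs)
    clusters = find_clusters(t_obs, df, config.alpha_pointwise, config.sidedness,
                             times=centers)

    # Sign flips leave sum(d^2) unchanged, so permuted t series follow from the
    # flipped means and the fixed second moment.
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    mean_perm = signs @ diffs / n                      # (perm, centers)
    msq = np.mean(diffs**2, axis=0)                    # sign-invariant
    var_perm = np.maximum(msq - mean_perm**2, 0.0) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_perm / np.sqrt(var_perm / n)
    t_perm[~np.isfinite(t_perm)] = 0.0
    null_max = _null_max_from_tmatrix(t_perm, thresh, two_sided=not one_sided)
    return _finalize(centers, t_obs, df, thresh, clusters, null_max,
                     two_sided=not one_sided, config=config)


def _two_sample_t(sum_a, ssq_a, n_a, sum_t, ssq_t, n_t):
    """Pooled-variance two-sample t from group A sums and overall totals."""
    n_b = n_t - n_a
    sum_b = sum_t - sum_a
    ssq_b = ssq_t - ssq_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = ssq_a - n_a * mean_a**2
    ss_b = ssq_b - n_b * mean_b**2
    sp2 = np.maximum(ss_a + ss_b, 0.0) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    zero = sp2 == 0
    t = np.where(zero & (diff > 0), np.inf, t)
    t = np.where(zero & (diff < 0), -np.inf, t)
    t = np.where(zero & (diff == 0), 0.0, t)
    return t


def cluster_test_groups(courses_a: list[SuppressionTimeCourse],
                        courses_b: list[SuppressionTimeCourse],
                        config: ClusterTestConfig | None = None
                        ) -> ClusterTestResult:
    """Cluster-corrected two-group comparison of suppression time courses.

    Pointwise pooled-variance two-sample t (two-sided by default); the null
    randomizes group membership with group sizes preserved and scores the maximum
    absolute cluster sum per permutation.
    """
    config = config or ClusterTestConfig(sidedness="two_sided",
                                         null_type="label_shuffle")
    if config.null_type != "label_shuffle":
        raise ValueError("the group test uses the label_shuffle null")
    _reject_smoothed(courses_a)
    _reject_smoothed(courses_b)
    if len(courses_a) < 2 or len(courses_b) < 2:
        raise ValueError("each group needs at least 2 participants")
    times, mat_a = _course_matrix(courses_a)
    times_b, mat_b = _course_matrix(courses_b)
    if times.size != times_b.size or not np.allclose(times, times_b):
        raise ValueError("groups must share a time grid")
    mat = np.vstack([mat_a, mat_b])
    n_a, n_t = mat_a.shape[0], mat.shape[0]
    df = n_t - 2
    two_sided = config.sidedness == "two_sided"
    thresh = stats.t.ppf(1 - (config.alpha_pointwise / 2 if two_sided
                              else config.alpha_pointwise), df)

    sum_t = mat.sum(axis=0)
    ssq_t = (mat**2).sum(axis=0)
    t_obs = _two_sample_t(mat_a.sum(axis=0), (mat_a**2).sum(axis=0), n_a,
                          sum_t, ssq_t, n_t)
    clusters = find_clusters(t_obs, df, config.alpha_pointwise, config.sidedness,
                             times=times)

    rng = np.random.default_rng(config.seed)
    t_perm = np.empty((config.n_permutations, times.size))
    idx = np.arange(n_t)
    for p in range(config.n_permutations):
        pick = rng.permutation(idx)[:n_a]
        sub = mat[pick]
        t_perm[p] = _two_sample_t(sub.sum(axis=0), (sub**2).sum(axis=0), n_a,
                                  sum_t, ssq_t, n_t)
    t_perm[~np.isfinite(t_perm)] = 0.0
    null_max = _null_max_from_tmatrix(t_perm, thresh, two_sided=two_sided)
    return _finalize(times, t_obs, df, thresh, clusters, null_max,
                     two_sided=two_sided, config=config)
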