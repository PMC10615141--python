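"""Simulation studies validating the pipeline against its own forward model.

These drivers power both the test suite and ``scripts/acceptance.py``:

* spectral exactness of the on-bin Fourier modulus;
* calibration of the complex-Mahalanobis exclusion rate under a clean Gaussian null
  (expected fraction at threshold 3: exp(-4.5) ~ 1.11%);
* the blur-cancellation diagnostic;
* family-wise type-I error of the two cluster permutation tests on null datasets
  (constant suppression, no reweighting);
* detection power and parameter recovery (time constant and asymptote of the
  suppressive-weight trajectory) on reweighting datasets.

Study problem sizes are the package's defaults for desk-scale validation: the
type-I study runs 20 participants with 8 trials per condition at 250 Hz (tagging
frequencies sit far below Nyquist, so results do not depend on the sampling rate);
the recovery study runs 40 participants with 48 trials per condition at 500 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import SimulationConfig, weight_for_db
from .spectral import fourier_coefficient, ComplexCoefficientSet
from .qc import complex_mahalanobis
from .cluster import ClusterTestConfig
from .metrics import pool_timecourses, SuppressionTimeCourse
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "onbin_modulus_error",
    "mahalanobis_null_fraction",
    "null_simulation_config",
    "reweighting_simulation_config",
    "type_one_error_study",
    "recovery_study",
    "fit_exponential_rise",
]


def onbin_modulus_error(n_draws: int = 50, seed: int = 0) -> float:
    """Worst-case |modulus - amplitude| for random on-bin sinusoids in a 1-s window.

    Random amplitudes, phases and integer frequencies; the projection is exact up to
    floating-point rounding, so this should sit near machine precision.
    """
    rng = np.random.default_rng(seed)
    fs = 1000.0
    t = np.arange(int(fs)) / fs
    worst = 0.0
    for _ in range(n_draws):
        f = float(rng.integers(1, 40))
        amp = float(rng.uniform(0.1, 10.0))
        phase = float(rng.uniform(0, 2 * np.pi))
        seg = amp * np.sin(2 * np.pi * f * t + phase)
        err = abs(abs(fourier_coefficient(seg, f, fs)) - amp)
        worst = max(worst, err)
    return worst


def mahalanobis_null_fraction(n_trials: int = 50_000, threshold: float = 3.0,
                              seed: int = 0) -> float:
    """Exclusion fraction of clean bivariate-Gaussian coefficients at a threshold."""
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(size=n_trials) + 1j * rng.normal(size=n_trials)
    cset = ComplexCoefficientSet(coefficients=coeffs[:, None],
                                 frequencies=[5.0],
                                 conditions=["alone_f1"] * n_trials,
                                 window=(0.0, 1.0))
    d = complex_mahalanobis(cset, 5.0)
    return float(np.mean(d > threshold))


# ----------------------------------------------------------------------
# simulation configurations for the studies
# ----------------------------------------------------------------------

def null_simulation_config(seed: int, n_participants: int = 20,
                           n_trials: int = 8,
                           sample_rate: float = 250.0) -> SimulationConfig:
    """No-reweighting dataset: the suppressive weight is constant (w0 == w_inf).

    Suppression is present (1.5 dB) but does not change over time, so the
    increasing-suppression test has nothing to find; half the participants are
    labelled into each of two arbitrary groups for the group-test null.
    """
    w = weight_for_db(1.5)
    groups = ["A" if i % 2 == 0 else "B" for i in range(n_participants)]
    return SimulationConfig(
        sample_rate=sample_rate, n_participants=n_participants,
        n_trials_per_condition=n_trials,
        w0=w, w_inf_mon=w, w_inf_dich=w,
        group_labels=groups, seed=seed)


def reweighting_simulation_config(seed: int, n_participants: int = 40,
                                  n_trials: int = 48, asymptote_db: float = 1.5,
                                  tau: float = 1.5,
                                  sample_rate: float = 500.0) -> SimulationConfig:
    """Reweighting dataset: weight rises from 0 toward the stated dB asymptote."""
    w_inf = weight_for_db(asymptote_db)
    return SimulationConfig(
        sample_rate=sample_rate, n_participants=n_participants,
        n_trials_per_condition=n_trials,
        w0=0.0, w_inf_mon=w_inf, w_inf_dich=w_inf, tau=tau, seed=seed)


def _study_pipeline_config(sim: SimulationConfig, n_permutations: int,
                           cluster_seed: int, step_s: float = 0.02,
                           group: bool = False) -> PipelineConfig:
    return PipelineConfig(
        simulation=sim, step_s=step_s,
        include_intermodulation=False, per_condition_tests=False,
        cluster=ClusterTestConfig(n_permutations=n_permutations, seed=cluster_seed),
        group_by="group_label" if group else None,
        seed=sim.seed)


def type_one_error_study(n_datasets: int = 200, n_permutations: int = 500,
                         n_participants: int = 20, n_trials: int = 8,
                         seed: int = 0) -> dict:
    """Family-wise false-positive rates of both cluster tests on null datasets.

    Each dataset has constant suppression (no reweighting) and arbitrary group
    labels; a dataset counts as a false positive when a test reports any significant
    cluster.  Nominal rate: 0.05.
    """
    root = np.random.SeedSequence(seed)
    increase_hits = 0
    group_hits = 0
    for child in root.spawn(n_datasets):
        s1, s2 = child.generate_state(2) % (2**31)
        sim = null_simulation_config(int(s1), n_participants, n_trials)
        cfg = _study_pipeline_config(sim, n_permutations, int(s2), group=True)
        result = run_pipeline(cfg)
        if result.cluster_increase["pooled"].significant_clusters:
            increase_hits += 1
        if result.cluster_groups.significant_clusters:
            group_hits += 1
    return {"n_datasets": n_datasets,
            "increase_rate": increase_hits / n_datasets,
            "groups_rate": group_hits / n_datasets}


def fit_exponential_rise(times: np.ndarray, ratio_db: np.ndarray
                         ) -> tuple[float, float, float]:
    """Least-squares fit of s(t) = s0 + (s_inf - s0) * (1 - exp(-t/tau)).

    Returns (s0, s_inf, tau).  Used to recover the reweighting time constant and
    asymptote from a group-mean suppression course.
    """
    def model(t, s0, s_inf, tau):
        return s0 + (s_inf - s0) * (1.0 - np.exp(-t / tau))

    p0 = (float(ratio_db[0]), float(ratio_db[-1]), 1.0)
    bounds = ([-5.0, -5.0, 0.05], [8.0, 8.0, 20.0])
    popt, _ = curve_fit(model, times, ratio_db, p0=p0, bounds=bounds, maxfev=20000)
    return tuple(float(v) for v in popt)


def recovery_study(n_seeds: int = 20, asymptote_db: float = 1.5, tau: float = 1.5,
                   n_participants: int = 40, n_trials: int = 48,
                   n_permutations: int = 1000, seed: int = 0) -> dict:
    """Detection power and parameter recovery on reweighting datasets.

    Per seed: simulate, run the pipeline, test for increasing suppression, and fit
    the exponential-rise model to the group-mean pooled course (window centers fully
    inside stimulation).  Detection requires a significant increasing cluster that
    begins within 3 time constants of onset.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for child in root.spawn(n_seeds):
        s1, s2 = child.generate_state(2) % (2**31)
        sim = reweighting_simulation_config(int(s1), n_participants, n_trials,
                                            asymptote_db, tau)
        cfg = _study_pipeline_config(sim, n_permutations, int(s2))
        result = run_pipeline(cfg)
        test = result.cluster_increase["pooled"]
        detected = any(c.start_s <= 3.0 * tau for c in test.significant_clusters)

        lo = cfg.window_s / 2
        hi = sim.trial_duration - lo
        pooled = [c.restrict(lo, hi) for c in result.pooled_courses]
        mean_course = pool_timecourses(pooled, label="group_mean")
        s0, s_inf, tau_hat = fit_exponential_rise(mean_course.times,
                                                  mean_course.ratio_db)
        rows.append({"detected": bool(detected), "tau_hat": tau_hat,
                     "asymptote_hat_db": s_inf,
                     "effect_size_d": float(result.effect_size.cohen_d),
                     "exclusion_fraction": result.manifest.exclusion_fraction})
    taus = np.array([r["tau_hat"] for r in rows])
    asym = np.array([r["asymptote_hat_db"] for r in rows])
    ok = np.array([
        r["detected"]
        and abs(r["tau_hat"] - tau) <= 0.3 * tau
        and abs(r["asymptote_hat_db"] - asymptote_db) <= 0.2
        for r in rows])
    return {"n_seeds": n_seeds, "true_tau": tau, "true_asymptote_db": asymptote_db,
            "detection_rate": float(np.mean([r["detected"] for r in rows])),
            "joint_success_rate": float(ok.mean()),
            "tau_hat_mean": float(taus.mean()),
            "asymptote_hat_mean_db": float(asym.mean()),
            "effect_size_d_mean": float(np.mean([r["effect_size_d"] for r in rows])),
            "per_seed": rows}
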