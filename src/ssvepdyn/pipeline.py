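"""End-to-end orchestration: simulate/load -> QC -> time courses -> ratios -> stats.

`run_pipeline` drives the full analysis from a single config and writes tidy CSV
tables, JSON results, and a run manifest.  `blur_cancellation_diagnostic` hosts the
analysis-validation simulation: a constant gain applied to the masked condition from
stimulus onset must come back as a constant dB ratio at every window center, because
the sliding window blurs the numerator and denominator identically and the blur
cancels in the ratio.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import SimulationConfig, generate_dataset
from .epochs_io import EpochedRecording, ChannelSet, TrialWaveform, average_channels, read_dataset
from .spectral import (AmplitudeTimeCourse, coherent_average, sliding_timecourse,
                       trial_coefficients, timecourses_frame)
from .qc import reject_outliers, OutlierReport
from .metrics import (DEFAULT_FLOOR_UV, SuppressionTimeCourse, suppression_ratio,
                      pool_timecourses, window_effect_size, intermodulation_timecourse,
                      suppression_frame)
from .cluster import ClusterTestConfig, cluster_test_increase, cluster_test_groups

__all__ = [
    "PipelineConfig",
    "PipelineConfigError",
    "ParticipantAnalysis",
    "PipelineResult",
    "RunManifest",
    "analyze_recording",
    "run_pipeline",
    "blur_cancellation_diagnostic",
    "BlurDiagnosticReport",
    "group_split",
]

#: (alone condition, masked condition, mask type) pairings for suppression ratios.
MASK_PAIRS = (
    ("plaid_mon", "monocular"),
    ("plaid_dich", "dichoptic"),
)


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (raised before any compute)."""


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Either ``simulation`` (a :class:`SimulationConfig`) or ``input_dir`` (a directory
    of epochs containers) must be set.  ``frequencies`` are the tagging fundamentals;
    harmonics (2*f) and the sum intermodulation term (f1+f2) are toggled separately.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    channels: list[str] | None = None      # None: average all channels
    frequencies: tuple[float, float] = (5.0, 7.0)
    include_harmonics: bool = False
    include_intermodulation: bool = True
    window_s: float = 1.0
    step_s: float = 0.01
    mahal_threshold: float = 3.0
    mahal_joint: bool = False
    floor_uv: float = DEFAULT_FLOOR_UV
    effect_early: tuple[float, float] = (0.0, 1.0)
    effect_late: tuple[float, float] = (3.0, 4.0)
    cluster: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    per_condition_tests: bool = True       # also test each frequency x mask course
    group_by: str | None = None            # 'group_label' to use recording labels
    out_dir: str | None = None
    save_epochs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise PipelineConfigError("set exactly one of simulation / input_dir")
        if len(self.frequencies) != 2:
            raise PipelineConfigError("frequencies must be the two tagging fundamentals")
        if self.window_s <= 0 or self.step_s <= 0:
            raise PipelineConfigError("window_s and step_s must be positive")
        if self.simulation is not None:
            sim = self.simulation
            if self.window_s > sim.trial_duration:
                raise PipelineConfigError("window_s exceeds the trial duration")
            nyq = sim.sample_rate / 2
            top = max(self.frequencies) * (2 if self.include_harmonics else 1)
            if self.include_intermodulation:
                top = max(top, sum(self.frequencies))
            if top >= nyq:
                raise PipelineConfigError("analysis frequencies reach Nyquist")
            if self.effect_late[1] > sim.trial_duration:
                raise PipelineConfigError("effect-size window outside stimulation period")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        clu = raw.pop("cluster", None)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulation"] = SimulationConfig(**sim)
        if clu is not None:
            kwargs["cluster"] = ClusterTestConfig(**clu)
        for key in ("frequencies", "effect_early", "effect_late"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("simulation", "cluster")}
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        d["cluster"] = dict(self.cluster.__dict__)
        for key in ("frequencies", "effect_early", "effect_late"):
            d[key] = list(d[key])
        return d


@dataclass
class ParticipantAnalysis:
    participant_id: str
    group_label: str | None
    qc_report: OutlierReport
    amplitude_courses: list[AmplitudeTimeCourse]
    suppression_courses: list[SuppressionTimeCourse]
    pooled: SuppressionTimeCourse
    im_courses: list          # IntermodulationTimeCourse per mask type


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)     # name -> {wall_s, **counts}
    outputs: dict = field(default_factory=dict)    # filename -> sha256
    exclusion_fraction: float | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


@dataclass
class PipelineResult:
    participants: list[ParticipantAnalysis]
    cluster_increase: dict                        # name -> ClusterTestResult
    effect_size: object
    cluster_groups: object | None
    manifest: RunManifest
    ground_truth: object | None = None

    @property
    def pooled_courses(self) -> list[SuppressionTimeCourse]:
        return [p.pooled for p in self.participants]


def _analysis_plan(config: PipelineConfig):
    """(frequency, alone condition) pairs whose suppression courses are computed."""
    f1, f2 = config.frequencies
    plan = [(f1, "alone_f1"), (f2, "alone_f2")]
    if config.include_harmonics:
        plan += [(2 * f1, "alone_f1"), (2 * f2, "alone_f2")]
    return plan


def _stim_interior(rec: EpochedRecording, config: PipelineConfig):
    """Window centers fully inside the stimulation period."""
    half = config.window_s / 2
    return half, rec.stim_duration - half


def analyze_recording(rec: EpochedRecording, config: PipelineConfig
                      ) -> ParticipantAnalysis:
    """Single-participant analysis: channel average, QC, time courses, ratios."""
    if config.window_s > rec.stim_duration:
        raise PipelineConfigError("window_s exceeds this recording's trial duration")
    waveforms = average_channels(rec, config.channels)
    coeffs = trial_coefficients(waveforms, list(config.frequencies),
                                interval=(0.0, rec.stim_duration))
    retained, report = reject_outliers(waveforms, coeffs,
                                       threshold=config.mahal_threshold,
                                       joint=config.mahal_joint)

    by_condition: dict[str, TrialWaveform] = {}
    for cond in dict.fromkeys(rec.condition_labels):
        cond_trials = [t for t in retained if t.condition == cond]
        if not cond_trials:
            raise ValueError(f"participant {rec.participant_id}: no trials left in "
                             f"condition {cond!r} after QC")
        by_condition[cond] = coherent_average(cond_trials)

    amp_courses: list[AmplitudeTimeCourse] = []
    course_at: dict[tuple[str, float], AmplitudeTimeCourse] = {}

    def course(cond: str, freq: float) -> AmplitudeTimeCourse:
        key = (cond, freq)
        if key not in course_at:
            tc = sliding_timecourse(by_condition[cond], freq,
                                    window_s=config.window_s, step_s=config.step_s)
            course_at[key] = tc
            amp_courses.append(tc)
        return course_at[key]

    suppression: list[SuppressionTimeCourse] = []
    for freq, alone_cond in _analysis_plan(config):
        for masked_cond, mask_type in MASK_PAIRS:
            if masked_cond not in by_condition:
                continue
            suppression.append(suppression_ratio(
                course(alone_cond, freq), course(masked_cond, freq),
                floor=config.floor_uv, mask_type=mask_type))

    pooled = pool_timecourses(suppression, label="pooled")

    im_courses = []
    if config.include_intermodulation:
        f_im = sum(config.frequencies)
        baselines = [course("alone_f1", f_im), course("alone_f2", f_im)]
        for masked_cond, mask_type in MASK_PAIRS:
            if masked_cond not in by_condition:
                continue
            im = intermodulation_timecourse(course(masked_cond, f_im), baselines,
                                            floor=config.floor_uv)
            im.mask_type = mask_type
            im_courses.append(im)

    return ParticipantAnalysis(
        participant_id=rec.participant_id, group_label=rec.group_label,
        qc_report=report, amplitude_courses=amp_courses,
        suppression_courses=suppression, pooled=pooled, im_courses=im_courses)


def group_split(metadata: dict, by: str = "median_score") -> dict[str, list]:
    """Split participants into two groups by a score median or diagnosis labels.

    ``metadata`` maps participant id -> score (median split: <= median goes to
    'low', > median to 'high') or -> label (diagnosis split: labels used verbatim).
    Participants with missing (None/NaN) values are dropped with a warning.
    """
    clean = {}
    for pid, value in metadata.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            warnings.warn(f"participant {pid} dropped from group split "
                          "(missing value)", stacklevel=2)
            continue
        clean[pid] = value
    if by == "median_score":
        med = float(np.median(list(clean.values())))
        groups = {"low": [p for p, v in clean.items() if v <= med],
                  "high": [p for p, v in clean.items() if v > med]}
    elif by == "diagnosis":
        groups = {}
        for pid, label in clean.items():
            groups.setdefault(str(label), []).append(pid)
    else:
        raise ValueError(f"unknown split {by!r}")
    empty = [k for k, v in groups.items() if not v]
    if empty or len(groups) < 2:
        raise ValueError(f"group split produced an empty or single group: {groups}")
    return groups


def _restricted(courses, lo, hi):
    return [c.restrict(lo, hi) for c in courses]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; write outputs if ``config.out_dir`` is set."""
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        version=__version__, seed=config.seed)

    t0 = time.perf_counter()
    truth = None
    if config.simulation is not None:
        recordings, truth = generate_dataset(config.simulation)
    else:
        recordings = read_dataset(config.input_dir)
    manifest.stages["load"] = {"wall_s": time.perf_counter() - t0,
                               "n_participants": len(recordings),
                               "n_trials": int(sum(r.n_trials for r in recordings))}

    t0 = time.perf_counter()
    participants = []
    for rec in recordings:
        try:
            participants.append(analyze_recording(rec, config))
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for participant {rec.participant_id}: {exc}") from exc
    excluded = sum(int(p.qc_report.excluded.sum()) for p in participants)
    total = sum(p.qc_report.excluded.size for p in participants)
    manifest.exclusion_fraction = excluded / total if total else None
    manifest.stages["analyze"] = {"wall_s": time.perf_counter() - t0,
                                  "n_trials_excluded": excluded,
                                  "n_trials_total": total}

    lo, hi = _stim_interior(recordings[0], config)
    pooled = _restricted([p.pooled for p in participants], lo, hi)

    t0 = time.perf_counter()
    cluster_results = {}
    effect = None
    if len(participants) >= 3:
        cluster_results["pooled"] = cluster_test_increase(pooled, config.cluster)
        if config.per_condition_tests:
            n_courses = len(participants[0].suppression_courses)
            for j in range(n_courses):
                c0 = participants[0].suppression_courses[j]
                name = f"{c0.frequency:g}hz_{c0.mask_type}"
                courses_j = _restricted(
                    [p.suppression_courses[j] for p in participants], lo, hi)
                cluster_results[name] = cluster_test_increase(courses_j, config.cluster)
    if len(participants) >= 2:
        effect = window_effect_size(pooled, early=config.effect_early,
                                    late=config.effect_late)
    manifest.stages["cluster_increase"] = {"wall_s": time.perf_counter() - t0,
                                           "n_tests": len(cluster_results)}

    t0 = time.perf_counter()
    groups_result = None
    if config.group_by == "group_label":
        labels = {p.participant_id: p.group_label for p in participants}
        groups = group_split(labels, by="diagnosis")
        names = sorted(groups)
        if len(names) != 2:
            raise ValueError(f"group comparison needs exactly 2 groups, got {names}")
        by_id = {p.participant_id: c for p, c in zip(participants, pooled)}
        cfg = ClusterTestConfig(lag=config.cluster.lag,
                                alpha_pointwise=config.cluster.alpha_pointwise,
                                n_permutations=config.cluster.n_permutations,
                                sidedness="two_sided", null_type="label_shuffle",
                                seed=config.cluster.seed)
        groups_result = cluster_test_groups([by_id[p] for p in groups[names[0]]],
                                            [by_id[p] for p in groups[names[1]]],
                                            cfg)
    manifest.stages["cluster_groups"] = {"wall_s": time.perf_counter() - t0}

    result = PipelineResult(participants=participants,
                            cluster_increase=cluster_results, effect_size=effect,
                            cluster_groups=groups_result, manifest=manifest,
                            ground_truth=truth)
    if config.out_dir is not None:
        _write_outputs(result, recordings, config)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: PipelineResult, recordings, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    written: list[Path] = []

    if config.save_epochs and config.simulation is not None:
        from .epochs_io import write_epochs
        for rec in recordings:
            written.extend(write_epochs(rec, out / "epochs"))
    if result.ground_truth is not None:
        p = out / "ground_truth.json"
        result.ground_truth.to_json(p)
        written.append(p)

    amp = timecourses_frame([c for part in result.participants
                             for c in part.amplitude_courses])
    p = out / "amplitude_timecourses.csv"
    amp.to_csv(p, index=False)
    written.append(p)

    sup_courses = [c for part in result.participants
                   for c in part.suppression_courses]
    sup_courses += [part.pooled for part in result.participants]
    p = out / "suppression_timecourses.csv"
    suppression_frame(sup_courses).to_csv(p, index=False)
    written.append(p)

    if any(part.im_courses for part in result.participants):
        frames = [pd.DataFrame({
            "participant": im.participant_id,
            "mask_type": getattr(im, "mask_type", None),
            "frequency_hz": im.frequency,
            "time_s": im.times,
            "im_index": im.index,
        }) for part in result.participants for im in part.im_courses]
        p = out / "intermodulation_timecourses.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        written.append(p)

    qc = pd.concat([part.qc_report.to_frame().assign(participant=part.participant_id)
                    for part in result.participants], ignore_index=True)
    p = out / "qc_report.csv"
    qc.to_csv(p, index=False)
    written.append(p)

    if result.effect_size is not None:
        p = out / "effect_size.json"
        result.effect_size.to_json(p)
        written.append(p)

    if result.cluster_increase:
        payload = {}
        for name, res in result.cluster_increase.items():
            tmp = out / f"_cluster_{name}.json"
            res.to_json(tmp)
            payload[name] = json.loads(tmp.read_text())
            tmp.unlink()
        p = out / "cluster_increase.json"
        p.write_text(json.dumps(payload, indent=2))
        written.append(p)

    if result.cluster_groups is not None:
        p = out / "cluster_groups.json"
        result.cluster_groups.to_json(p)
        written.append(p)

    result.manifest.stages["write"] = {"wall_s": time.perf_counter() - t0,
                                       "n_files": len(written) + 1}
    for p in written:
        result.manifest.outputs[str(p.relative_to(out))] = _sha256(p)
    result.manifest.to_json(out / "manifest.json")


# ----------------------------------------------------------------------
# blur-cancellation diagnostic
# ----------------------------------------------------------------------

@dataclass
class BlurDiagnosticReport:
    gain: float
    programmed_db: float
    times: np.ndarray
    ratio_db: np.ndarray
    alone_amplitudes: np.ndarray
    evaluated: np.ndarray            # mask of centers entering the deviation
    max_abs_deviation_db: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "gain": self.gain,
            "programmed_db": self.programmed_db,
            "max_abs_deviation_db": self.max_abs_deviation_db,
            "n_centers_evaluated": int(self.evaluated.sum()),
        }, indent=2))


def blur_cancellation_diagnostic(gain: float = 0.8, frequency: float = 5.0,
                                 amplitude: float = 2.0, sample_rate: float = 1000.0,
                                 epoch_pre: float = 1.5, trial_duration: float = 6.0,
                                 epoch_post: float = 1.5, window_s: float = 1.0,
                                 step_s: float = 0.01,
                                 floor: float = DEFAULT_FLOOR_UV
                                 ) -> BlurDiagnosticReport:
    """Verify the ratio undoes the sliding window's temporal blur.

    Simulates a noise-free alone condition (sinusoid present only during
    stimulation) and a masked condition that is the alone waveform scaled by a
    constant ``gain`` from onset.  The sliding window smears each amplitude course
    across ~1 s at onset, but the smearing is identical in numerator and denominator,
    so the estimated ratio must sit at ``-20*log10(gain)`` dB at every window center
    where signal is present — including windows straddling the onset.  Centers whose
    window contains no stimulation (both amplitudes at the floor) are excluded from
    the deviation.
    """
    n = int(round((epoch_pre + trial_duration + epoch_post) * sample_rate))
    t = np.arange(n) / sample_rate - epoch_pre
    stim = (t >= 0) & (t < trial_duration)
    sig = np.where(stim, amplitude * np.sin(2 * np.pi * frequency * t), 0.0)
    alone = TrialWaveform(samples=sig, time_zero=-epoch_pre, sample_rate=sample_rate,
                          condition="alone_f1")
    masked = TrialWaveform(samples=np.where(stim, gain * sig, sig),
                           time_zero=-epoch_pre, sample_rate=sample_rate,
                           condition="plaid_mon")
    tc_alone = sliding_timecourse(alone, frequency, window_s, step_s)
    tc_masked = sliding_timecourse(masked, frequency, window_s, step_s)
    ratio = suppression_ratio(tc_alone, tc_masked, floor=floor, mask_type="diagnostic")
    programmed = -20.0 * np.log10(gain)
    evaluated = tc_alone.amplitudes > 10 * floor
    dev = np.abs(ratio.ratio_db[evaluated] - programmed)
    return BlurDiagnosticReport(
        gain=gain, programmed_db=programmed, times=ratio.times,
        ratio_db=ratio.ratio_db, alone_amplitudes=tc_alone.amplitudes,
        evaluated=evaluated,
        max_abs_deviation_db=float(dev.max()) if dev.size else 0.0)
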