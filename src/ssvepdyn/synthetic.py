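"""Synthetic SSVEP generator based on a dynamic divisive-normalization forward model.

Two stimuli flicker at distinct tagging frequencies (5 and 7 Hz by default) and drive
phase-locked oscillatory responses at those frequencies, their second harmonics, and —
when both are present — a sum intermodulation term at ``f1 + f2``.  When the two stimuli
are shown together, each component's response is divisively suppressed by the other with
a suppressive weight that grows over the first seconds of stimulation:

    gain_i(t) = 1 / (1 + w(t) * m_i),      w(t) = w0 + (w_inf - w0) * (1 - exp(-t / tau))

where ``m_i`` is the competing component's drive (1 in plaid conditions, 0 when the
stimulus is shown alone).  The asymptotic weight differs between monocular
(superimposed, same eye) and dichoptic (opposite eye) mask arrangements.  The true
suppression in dB at time ``t`` is therefore ``20*log10(1 + w(t))``, the latent quantity
the analysis pipeline estimates.

Each epoch spans a pre-stimulus interval, the stimulation period, and a post-stimulus
interval, with 1/f^beta broadband noise throughout and elevated noise variance outside
the stimulation period (movement during breaks).  An optional multiplicative onset
transient and occasional large-amplitude artifact trials complete the picture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "ParticipantParams",
    "GroundTruth",
    "suppression_weight",
    "generate_trial",
    "generate_dataset",
    "weight_for_db",
]

#: Canonical condition labels: each tagged stimulus alone, and the two plaid
#: (target + mask) arrangements.
CONDITIONS = ("alone_f1", "alone_f2", "plaid_mon", "plaid_dich")


def weight_for_db(suppression_db: float) -> float:
    """Suppressive weight producing a given asymptotic suppression in dB.

    Inverts ``suppression_db = 20*log10(1 + w)`` (competing drive m = 1).
    """
    return 10.0 ** (suppression_db / 20.0) - 1.0


@dataclass
class SimulationConfig:
    """Parameters of the forward model.

    Defaults mirror the study design this generator emulates: 5 and 7 Hz sinusoidal
    flicker, 1 kHz sampling, 6-s trials with 3-s intertrial intervals, 48 trials per
    condition, and a suppressive weight rising with time constant ``tau`` toward
    mask-type-specific asymptotes.
    """

    f1: float = 5.0                     # Hz, first tagging frequency
    f2: float = 7.0                     # Hz, second tagging frequency
    sample_rate: float = 1000.0         # Hz
    trial_duration: float = 6.0         # s of stimulation
    iti_duration: float = 3.0           # s between trials (noise-only context)
    epoch_pre: float = 1.5              # s of epoch before stimulus onset
    epoch_post: float = 1.5             # s of epoch after stimulus offset
    n_participants: int = 10
    n_trials_per_condition: int = 48
    response_amplitude_mean: float = 4.0   # uV, across participants
    response_amplitude_sd: float = 1.5     # uV
    w0: float = weight_for_db(0.5)         # initial suppressive weight (~0.5 dB)
    w_inf_mon: float = weight_for_db(1.5)  # asymptotic weight, monocular mask
    w_inf_dich: float = weight_for_db(2.5) # asymptotic weight, dichoptic mask
    tau: float = 1.5                    # s, reweighting time constant
    harmonic_gain: float = 0.25         # second-harmonic amplitude as fraction of fundamental
    im_gain: float = 0.2                # f1+f2 amplitude as fraction of participant amplitude
    noise_exponent: float = 1.0         # beta of the 1/f^beta broadband noise
    noise_sd: float = 1.0               # uV during stimulation
    iti_noise_multiplier: float = 2.0   # noise VARIANCE multiplier outside stimulation
    transient_amplitude: float = 0.5    # onset burst: fractional amplitude boost at t=0
    transient_decay: float = 0.2        # s, decay constant of the onset burst
    artifact_rate: float = 0.0          # fraction of trials replaced by artifacts
    n_channels: int = 1
    channel_names: Sequence[str] | None = None
    group_labels: Sequence[str] | None = None   # optional per-participant labels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f1 == self.f2:
            raise ValueError("f1 and f2 must differ")
        for f in (self.f1, self.f2):
            if abs(f - round(f)) > 1e-9:
                raise ValueError(
                    f"tagging frequency {f} Hz must be an integer number of cycles per "
                    "second so a 1-s window holds an exact number of cycles"
                )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("trial_duration", "iti_duration", "epoch_pre", "epoch_post",
                     "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        if self.iti_noise_multiplier < 1.0:
            raise ValueError("iti_noise_multiplier must be >= 1")
        if max(2 * self.f1, 2 * self.f2, self.f1 + self.f2) >= self.sample_rate / 2:
            raise ValueError("all modelled components must lie below Nyquist")
        if self.channel_names is None:
            base = ["Oz", "POz", "O1", "O2"]
            if self.n_channels <= 4:
                self.channel_names = base[: self.n_channels]
            else:
                self.channel_names = base + [f"ch{i}" for i in range(4, self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if self.group_labels is not None and len(self.group_labels) != self.n_participants:
            raise ValueError("group_labels length must equal n_participants")

    # -- derived geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_pre + self.trial_duration + self.epoch_post)
                         * self.sample_rate))

    @property
    def onset_index(self) -> int:
        return int(round(self.epoch_pre * self.sample_rate))

    @property
    def offset_index(self) -> int:
        return int(round((self.epoch_pre + self.trial_duration) * self.sample_rate))

    def weight_params(self, mask_type: str) -> tuple[float, float, float]:
        """(w0, w_inf, tau) for a mask type ('monocular' or 'dichoptic')."""
        if mask_type == "monocular":
            return (self.w0, self.w_inf_mon, self.tau)
        if mask_type == "dichoptic":
            return (self.w0, self.w_inf_dich, self.tau)
        raise ValueError(f"unknown mask type: {mask_type!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_names"] = list(self.channel_names)
        if self.group_labels is not None:
            d["group_labels"] = list(self.group_labels)
        return d


@dataclass
class ParticipantParams:
    """Latent per-participant parameters drawn by :func:`generate_dataset`."""

    participant_id: str
    amplitude: float            # uV, fundamental response amplitude
    phase_f1: float             # rad
    phase_f2: float             # rad


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must estimate."""

    participants: list[ParticipantParams]
    weight_params: dict            # mask_type -> (w0, w_inf, tau)
    tau: float
    asymptotic_db: dict            # mask_type -> 20*log10(1 + w_inf)
    artifact_trials: dict          # participant_id -> sorted list of trial indices
    config: SimulationConfig

    def suppression_db(self, t, mask_type: str):
        """True instantaneous suppression (dB) at time ``t`` s after onset."""
        w0, w_inf, tau = self.weight_params[mask_type]
        w = suppression_weight(t, w0, w_inf, tau)
        return 20.0 * np.log10(1.0 + w)

    def to_json(self, path) -> None:
        payload = {
            "participants": [asdict(p) for p in self.participants],
            "weight_params": {k: list(v) for k, v in self.weight_params.items()},
            "tau": self.tau,
            "asymptotic_db": self.asymptotic_db,
            "artifact_trials": {k: list(map(int, v)) for k, v in self.artifact_trials.items()},
            "config": self.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def suppression_weight(t, w0: float, w_inf: float, tau: float):
    """Suppressive weight trajectory: exponential approach from ``w0`` to ``w_inf``.

    Returns ``w0`` for ``t <= 0`` and ``w0 + (w_inf - w0) * (1 - exp(-t/tau))`` after
    onset.  Accepts scalars or arrays of times in seconds.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    w = w0 + (w_inf - w0) * (1.0 - np.exp(-np.clip(t, 0.0, None) / tau))
    out = np.where(t <= 0, w0, w)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# noise synthesis
# ----------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                beta: float, sd: float) -> np.ndarray:
    """1/f^beta Gaussian noise with per-sample standard deviation ``sd``.

    White Gaussian noise is shaped in the frequency domain by f^(-beta/2) (DC removed)
    with an analytic renormalization so the output variance equals sd^2 regardless of
    beta or segment length.
    """
    if sd == 0:
        return np.zeros(shape + (n_samples,))
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)          # cycles/sample; absolute scale irrelevant
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    # Parseval weights: interior rfft bins represent two conjugate FFT bins.
    weights = np.full_like(freqs, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    norm = np.sqrt((weights * shaping**2).sum() / n_samples)
    spec *= shaping / norm
    return sd * np.fft.irfft(spec, n=n_samples, axis=-1)


# ----------------------------------------------------------------------
# signal construction
# ----------------------------------------------------------------------

def _condition_signal(config: SimulationConfig, condition: str,
                      params: ParticipantParams) -> np.ndarray:
    """Noiseless single-channel waveform for one condition (length n_samples)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition label: {condition!r}")

    n = config.n_samples
    fs = config.sample_rate
    t = np.arange(n) / fs - config.epoch_pre      # s relative to stimulus onset
    stim = (t >= 0) & (t < config.trial_duration)
    ts = t[stim]

    plaid = condition.startswith("plaid")
    if plaid:
        mask_type = "monocular" if condition == "plaid_mon" else "dichoptic"
        w = suppression_weight(ts, *config.weight_params(mask_type))
        gain = 1.0 / (1.0 + w)          # competing drive m = 1
    else:
        gain = np.ones_like(ts)         # m = 0: no suppression

    transient = 1.0 + config.transient_amplitude * np.exp(-ts / config.transient_decay)

    components: list[tuple[float, float, float]] = []   # (freq, amplitude, phase)
    amp = params.amplitude
    if plaid or condition == "alone_f1":
        components.append((config.f1, amp, params.phase_f1))
        components.append((2 * config.f1, config.harmonic_gain * amp, 2 * params.phase_f1))
    if plaid or condition == "alone_f2":
        components.append((config.f2, amp, params.phase_f2))
        components.append((2 * config.f2, config.harmonic_gain * amp, 2 * params.phase_f2))

    sig = np.zeros(n)
    for freq, a, phase in components:
        sig[stim] += a * gain * transient * np.sin(2 * np.pi * freq * ts + phase)
    if plaid and config.im_gain > 0:
        im_phase = params.phase_f1 + params.phase_f2
        sig[stim] += (config.im_gain * amp * transient
                      * np.sin(2 * np.pi * (config.f1 + config.f2) * ts + im_phase))
    return sig


def generate_trial(config: SimulationConfig, condition: str,
                   params: ParticipantParams,
                   rng: np.random.Generator) -> np.ndarray:
    """One epoched trial (channels x samples) for a given condition and participant.

    Channel 0 carries the tagged response plus noise; additional channels (if
    configured) carry independent noise realizations of the same signal.  Deterministic
    given the generator state.
    """
    sig = _condition_signal(config, condition, params)
    noise = _pink_noise(rng, (config.n_channels,), config.n_samples,
                        config.noise_exponent, config.noise_sd)
    if config.iti_noise_multiplier > 1.0 and config.noise_sd > 0:
        iti = np.ones(config.n_samples)
        iti[: config.onset_index] = np.sqrt(config.iti_noise_multiplier)
        iti[config.offset_index:] = np.sqrt(config.iti_noise_multiplier)
        noise *= iti
    return sig[None, :] + noise


def _artifact_trial(config: SimulationConfig, params: ParticipantParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Large-amplitude broadband segment standing in for a movement artifact."""
    sd = 10.0 * params.amplitude
    return _pink_noise(rng, (config.n_channels,), config.n_samples,
                       config.noise_exponent, sd)


def generate_dataset(config: SimulationConfig):
    """Simulate the full study: one epoched recording per participant.

    Returns ``(recordings, ground_truth)`` where ``recordings`` is a list of
    :class:`~ssvepdyn.epochs_io.EpochedRecording` (one per participant, with
    ``n_trials_per_condition`` trials of each of the four conditions in shuffled order)
    and ``ground_truth`` records the latent parameters and artifact-trial indices.
    Bit-reproducible for a fixed ``config.seed``.
    """
    from .epochs_io import EpochedRecording   # local import to avoid a cycle

    root = np.random.SeedSequence(config.seed)
    participant_seeds = root.spawn(config.n_participants)

    recordings = []
    participants = []
    artifact_trials: dict[str, list[int]] = {}

    n_trials = config.n_trials_per_condition * len(CONDITIONS)
    for p_idx, seq in enumerate(participant_seeds):
        rng = np.random.default_rng(seq)
        pid = f"P{p_idx:03d}"
        amp = max(0.5, rng.normal(config.response_amplitude_mean,
                                  config.response_amplitude_sd))
        params = ParticipantParams(
            participant_id=pid,
            amplitude=float(amp),
            phase_f1=float(rng.uniform(0, 2 * np.pi)),
            phase_f2=float(rng.uniform(0, 2 * np.pi)),
        )
        participants.append(params)

        labels = np.repeat(CONDITIONS, config.n_trials_per_condition)
        rng.shuffle(labels)

        # Noiseless condition templates, then fresh noise per trial (vectorized).
        templates = {c: _condition_signal(config, c, params) for c in CONDITIONS}
        noise = _pink_noise(rng, (n_trials, config.n_channels), config.n_samples,
                            config.noise_exponent, config.noise_sd)
        if config.iti_noise_multiplier > 1.0 and config.noise_sd > 0:
            scale = np.sqrt(config.iti_noise_multiplier)
            noise[..., : config.onset_index] *= scale
            noise[..., config.offset_index:] *= scale
        data = noise
        for c in CONDITIONS:
            data[labels == c] += templates[c][None, None, :]

        flagged: list[int] = []
        if config.artifact_rate > 0:
            is_artifact = rng.random(n_trials) < config.artifact_rate
            for idx in np.nonzero(is_artifact)[0]:
                data[idx] = _artifact_trial(config, params, rng)
                flagged.append(int(idx))
        artifact_trials[pid] = flagged

        group = config.group_labels[p_idx] if config.group_labels is not None else None
        recordings.append(EpochedRecording(
            data=data.astype(np.float32),
            sample_rate=config.sample_rate,
            onset_index=config.onset_index,
            offset_index=config.offset_index,
            condition_labels=[str(c) for c in labels],
            participant_id=pid,
            group_label=group,
            channel_names=list(config.channel_names),
        ))

    truth = GroundTruth(
        participants=participants,
        weight_params={
            "monocular": config.weight_params("monocular"),
            "dichoptic": config.weight_params("dichoptic"),
        },
        tau=config.tau,
        asymptotic_db={
            "monocular": 20.0 * np.log10(1.0 + config.w_inf_mon),
            "dichoptic": 20.0 * np.log10(1.0 + config.w_inf_dich),
        },
        artifact_trials=artifact_trials,
        config=config,
    )
    return recordings, truth
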