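"""Epochs container I/O and channel handling.

The on-disk container is one binary float32 array file (``<pid>_epochs.npy``, shape
trials x channels x samples) plus a JSON sidecar (``<pid>_epochs.json``) holding the
sampling rate, condition labels, onset/offset sample indices, channel names and
participant/group identifiers.  Single trials can also round-trip through delimited
text (CSV, one row per sample, one column per channel) for interoperability with
spreadsheet-style exports.

Times downstream are seconds relative to stimulus onset (onset = 0); epoch sample 0
maps to ``-onset_index / sample_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CONDITIONS

__all__ = [
    "EpochedRecording",
    "ChannelSet",
    "TrialWaveform",
    "write_epochs",
    "read_epochs",
    "read_dataset",
    "average_channels",
    "write_trial_csv",
    "read_trial_csv",
    "trial_waveforms_frame",
]


class EpochsIOError(ValueError):
    """Raised when a container fails validation on read or write."""


@dataclass
class EpochedRecording:
    """Epoched multichannel trials for one participant.

    data
        Array of shape (trials, channels, samples), microvolts.
    onset_index / offset_index
        Sample indices of stimulus onset and offset within each epoch.
    """

    data: np.ndarray
    sample_rate: float
    onset_index: int
    offset_index: int
    condition_labels: list[str]
    participant_id: str
    group_label: str | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise EpochsIOError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_channels)]
        if len(self.channel_names) != n_channels:
            raise EpochsIOError("channel_names length must match channel axis")
        if len(self.condition_labels) != n_trials:
            raise EpochsIOError(
                f"{len(self.condition_labels)} condition labels for {n_trials} trials")
        unknown = set(self.condition_labels) - set(CONDITIONS)
        if unknown:
            raise EpochsIOError(f"unknown condition labels: {sorted(unknown)}")
        if not (0 <= self.onset_index < self.offset_index <= n_samples):
            raise EpochsIOError("require 0 <= onset_index < offset_index <= samples")
        if not np.all(np.isfinite(self.data)):
            raise EpochsIOError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds relative to stimulus onset."""
        return (np.arange(self.data.shape[2]) - self.onset_index) / self.sample_rate

    @property
    def stim_duration(self) -> float:
        return (self.offset_index - self.onset_index) / self.sample_rate

    def trial_indices(self, condition: str) -> np.ndarray:
        labels = np.asarray(self.condition_labels)
        return np.nonzero(labels == condition)[0]


@dataclass
class ChannelSet:
    """Named analysis channels resolved against a recording's channel axis."""

    names: list[str]

    def __post_init__(self) -> None:
        if not self.names:
            raise EpochsIOError("ChannelSet must name at least one channel")
        if len(set(self.names)) != len(self.names):
            raise EpochsIOError("duplicate channel names in ChannelSet")

    def resolve(self, rec: EpochedRecording) -> np.ndarray:
        indices = []
        for name in self.names:
            try:
                indices.append(rec.channel_names.index(name))
            except ValueError:
                raise EpochsIOError(
                    f"channel {name!r} not in recording (has {rec.channel_names})"
                ) from None
        return np.asarray(indices)


@dataclass
class TrialWaveform:
    """Channel-averaged waveform for one trial.

    ``time_zero`` is the time (s, relative to stimulus onset) of sample 0, so the
    stimulus onset sits at time 0 on this axis.
    """

    samples: np.ndarray
    time_zero: float
    sample_rate: float
    condition: str | None = None
    participant_id: str | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise EpochsIOError("TrialWaveform samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise EpochsIOError("TrialWaveform contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.time_zero + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


# ----------------------------------------------------------------------
# binary container
# ----------------------------------------------------------------------

def write_epochs(rec: EpochedRecording, out_dir) -> tuple[Path, Path]:
    """Write ``<pid>_epochs.npy`` + ``<pid>_epochs.json``; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / f"{rec.participant_id}_epochs.npy"
    sidecar_path = out_dir / f"{rec.participant_id}_epochs.json"
    np.save(data_path, rec.data.astype(np.float32))
    meta = {
        "participant_id": rec.participant_id,
        "group_label": rec.group_label,
        "sample_rate": rec.sample_rate,
        "n_trials": int(rec.data.shape[0]),
        "n_channels": int(rec.data.shape[1]),
        "n_samples": int(rec.data.shape[2]),
        "onset_index": int(rec.onset_index),
        "offset_index": int(rec.offset_index),
        "channel_names": rec.channel_names,
        "condition_labels": rec.condition_labels,
        "dtype": "float32",
        "data_file": data_path.name,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    return data_path, sidecar_path


def read_epochs(sidecar_path) -> EpochedRecording:
    """Read and validate one participant's container from its JSON sidecar."""
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise EpochsIOError(f"sidecar not found: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    required = {"participant_id", "sample_rate", "n_trials", "n_channels", "n_samples",
                "onset_index", "offset_index", "channel_names", "condition_labels",
                "data_file"}
    missing = required - meta.keys()
    if missing:
        raise EpochsIOError(f"sidecar missing keys: {sorted(missing)}")
    data_path = sidecar_path.parent / meta["data_file"]
    if not data_path.exists():
        raise EpochsIOError(f"data file not found: {data_path}")
    data = np.load(data_path)
    declared = (meta["n_trials"], meta["n_channels"], meta["n_samples"])
    if data.shape != declared:
        raise EpochsIOError(
            f"array shape {data.shape} does not match sidecar {declared}")
    return EpochedRecording(
        data=data,
        sample_rate=float(meta["sample_rate"]),
        onset_index=int(meta["onset_index"]),
        offset_index=int(meta["offset_index"]),
        condition_labels=list(meta["condition_labels"]),
        participant_id=str(meta["participant_id"]),
        group_label=meta.get("group_label"),
        channel_names=list(meta["channel_names"]),
    )


def read_dataset(directory) -> list[EpochedRecording]:
    """Read every ``*_epochs.json`` container in a directory, sorted by participant."""
    directory = Path(directory)
    sidecars = sorted(directory.glob("*_epochs.json"))
    if not sidecars:
        raise EpochsIOError(f"no epochs containers found in {directory}")
    return [read_epochs(p) for p in sidecars]


# ----------------------------------------------------------------------
# delimited text (single trial)
# ----------------------------------------------------------------------

def write_trial_csv(rec: EpochedRecording, trial: int, path) -> Path:
    """Export one trial as CSV: a time_s column plus one column per channel."""
    path = Path(path)
    frame = pd.DataFrame(rec.data[trial].T, columns=rec.channel_names)
    frame.insert(0, "time_s", rec.times)
    frame.to_csv(path, index=False)
    return path


def read_trial_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a single-trial CSV back to a (channels x samples) array + channel names."""
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise EpochsIOError("trial CSV must have a time_s column")
    channels = [c for c in frame.columns if c != "time_s"]
    return frame[channels].to_numpy().T, channels


# ----------------------------------------------------------------------
# channel averaging
# ----------------------------------------------------------------------

def average_channels(rec: EpochedRecording,
                     channels: ChannelSet | list[str] | None = None
                     ) -> list[TrialWaveform]:
    """Arithmetic mean over the named channels, per trial, trial order preserved.

    With ``channels=None`` all channels are averaged — the virtual-channel case.
    """
    if channels is None:
        channels = ChannelSet(list(rec.channel_names))
    elif not isinstance(channels, ChannelSet):
        channels = ChannelSet(list(channels))
    idx = channels.resolve(rec)
    time_zero = -rec.onset_index / rec.sample_rate
    averaged = rec.data[:, idx, :].mean(axis=1)
    return [
        TrialWaveform(samples=averaged[i], time_zero=time_zero,
                      sample_rate=rec.sample_rate,
                      condition=rec.condition_labels[i],
                      participant_id=rec.participant_id, trial_index=i)
        for i in range(rec.n_trials)
    ]


def trial_waveforms_frame(waveforms: list[TrialWaveform]) -> pd.DataFrame:
    """Tidy frame of trial waveforms: participant, trial, condition, time_s, amplitude_uv."""
    parts = []
    for w in waveforms:
        parts.append(pd.DataFrame({
            "participant": w.participant_id,
            "trial": w.trial_index,
            "condition": w.condition,
            "time_s": w.times,
            "amplitude_uv": w.samples,
        }))
    return pd.concat(parts, ignore_index=True)
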