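"""In-memory containers for continuous EEG, trial event tables and epochs.

The containers are deliberately thin: plain NumPy arrays with light
validation, so every pipeline stage can operate on them without format
round-trips. File I/O (EDF/BrainVision readers, the internal ``.npz``
session container, events CSV) lives in :mod:`vmil.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["EEGRecording", "TrialEvents", "EpochSet"]


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One label per channel.
    reference : str
        Reference scheme; ``"CAR"`` after common-average re-referencing.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains NaN or Inf")
        self.channel_labels = list(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        """Return a shallow copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass
class TrialEvents:
    """Per-trial event markers and endpoint geometry.

    All onsets are 0-based sample indices into the recording. ``reached_sample``
    is the sample at which the effector entered the target zone; for trials
    that ran into the movement time limit the timeout flag is set and
    ``reached_sample`` marks the end of the limit window.
    """

    baseline_onset: np.ndarray
    planning_onset: np.ndarray
    go_onset: np.ndarray
    reached_sample: np.ndarray
    timeout: np.ndarray
    start_pos: np.ndarray  # (n_trials, 3), metres
    target_pos: np.ndarray  # (n_trials, 3), metres
    fs: float
    go_limit: float = 10.0  # seconds

    def __post_init__(self) -> None:
        self.baseline_onset = np.asarray(self.baseline_onset, dtype=np.int64)
        self.planning_onset = np.asarray(self.planning_onset, dtype=np.int64)
        self.go_onset = np.asarray(self.go_onset, dtype=np.int64)
        self.reached_sample = np.asarray(self.reached_sample, dtype=np.int64)
        self.timeout = np.asarray(self.timeout, dtype=bool)
        self.start_pos = np.atleast_2d(np.asarray(self.start_pos, dtype=float))
        self.target_pos = np.atleast_2d(np.asarray(self.target_pos, dtype=float))
        n = len(self.baseline_onset)
        for name in ("planning_onset", "go_onset", "reached_sample", "timeout"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != {n}")
        if self.start_pos.shape != (n, 3) or self.target_pos.shape != (n, 3):
            raise ValueError("start_pos/target_pos must have shape (n_trials, 3)")
        # within-trial ordering and non-overlap across trials
        within = (
            (self.baseline_onset < self.planning_onset)
            & (self.planning_onset < self.go_onset)
            & (self.go_onset <= self.reached_sample)
        )
        if not np.all(within):
            bad = int(np.flatnonzero(~within)[0])
            raise ValueError(f"non-increasing phase onsets in trial {bad}")
        if n > 1 and np.any(self.baseline_onset[1:] < self.reached_sample[:-1]):
            raise ValueError("trials overlap")

    @property
    def n_trials(self) -> int:
        return len(self.baseline_onset)

    @property
    def distances(self) -> np.ndarray:
        """Start-to-target Euclidean distance per trial (m)."""
        return np.linalg.norm(self.target_pos - self.start_pos, axis=1)


@dataclass
class EpochSet:
    """Equal-length epochs cut from a continuous recording.

    ``epochs`` has shape (n_trials, n_rows, n_samples) where rows are either
    channels or independent components.
    """

    epochs: np.ndarray
    phase: str
    fs: float
    trial_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    row_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials x rows x samples)")
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.epochs.shape[0])
        self.trial_indices = np.asarray(self.trial_indices, dtype=np.int64)
        if len(self.trial_indices) != self.epochs.shape[0]:
            raise ValueError("trial index count != epoch count")
        if len(np.unique(self.trial_indices)) != len(self.trial_indices):
            raise ValueError("trial indices must be unique")
        if not np.all(np.diff(self.trial_indices) > 0):
            raise ValueError("trial indices must be sorted")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]
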