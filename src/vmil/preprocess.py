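"""Referencing, filtering, epoching and pooled dimensionality reduction.

The preprocessing chain mirrors standard multi-subject EEG source-separation
practice: common average reference per recording, zero-phase Butterworth
high-pass, pooling all subjects in time, and PCA reduction of the pooled
data. PCA scores can be whitened (unit variance per component), which is the
input contract of the SOBI joint diagonalization that follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording, EpochSet, TrialEvents

__all__ = [
    "rereference_car",
    "highpass",
    "extract_epochs",
    "PooledPCA",
    "pool_and_reduce",
]

#: epoch durations (seconds) per trial phase: the baseline is fixed-length,
#: planning epochs take the guaranteed minimum of the variable phase duration
PHASE_EPOCH_SECONDS = {"baseline": 5.0, "planning": 2.5}


def rereference_car(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: subtract the instantaneous mean
    across channels, making every sample zero-mean over channels."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data.astype(rec.data.dtype), reference="CAR")


def highpass(
    rec: EEGRecording, cutoff_hz: float, order: int = 3, zero_phase: bool = True
) -> EEGRecording:
    """Butterworth high-pass per channel.

    Applied forward-backward (zero-phase) by default so epoch timing is not
    distorted; note this doubles the effective filter order.
    """
    if cutoff_hz >= rec.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {rec.fs / 2} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.fs)
    if zero_phase:
        out = sps.filtfilt(b, a, rec.data, axis=1)
    else:
        out = sps.lfilter(b, a, rec.data, axis=1)
    return rec.copy_with(data=out.astype(rec.data.dtype))


def extract_epochs(
    rec: EEGRecording,
    events: TrialEvents,
    phase: str,
    duration: float | None = None,
) -> EpochSet:
    """Cut equal-length epochs for one trial phase.

    ``duration`` defaults to :data:`PHASE_EPOCH_SECONDS` for the phase
    (baseline: 5 s; planning: first 2.5 s, the minimum planning duration,
    so variable-length planning phases yield equal-length epochs).
    """
    if phase not in ("baseline", "planning"):
        raise ValueError(f"phase must be 'baseline' or 'planning', got {phase!r}")
    if duration is None:
        duration = PHASE_EPOCH_SECONDS[phase]
    onsets = events.baseline_onset if phase == "baseline" else events.planning_onset
    n_samp = int(round(duration * rec.fs))
    ends = onsets + n_samp
    if np.any(onsets < 0) or np.any(ends > rec.n_samples):
        bad = int(np.flatnonzero((onsets < 0) | (ends > rec.n_samples))[0])
        raise ValueError(
            f"{phase} window of trial {bad} exceeds the recording bounds"
        )
    idx = onsets[:, None] + np.arange(n_samp)[None, :]
    epochs = rec.data[:, idx].transpose(1, 0, 2)  # trials x channels x samples
    return EpochSet(
        epochs=epochs,
        phase=phase,
        fs=rec.fs,
        trial_indices=np.arange(events.n_trials),
        row_labels=list(rec.channel_labels),
    )


@dataclass
class PooledPCA:
    """PCA of time-pooled multi-subject EEG.

    ``components_`` rows are orthonormal channel-space eigenvectors ordered by
    decreasing explained variance; ``explained_variance_`` are the matching
    eigenvalues. ``transform`` optionally whitens the scores to unit variance,
    the form SOBI consumes. ``boundaries`` holds the cumulative sample offsets
    of each subject inside the pooled score matrix.
    """

    components_: np.ndarray  # (n_components, n_channels), orthonormal rows
    mean_: np.ndarray  # (n_channels,)
    explained_variance_: np.ndarray  # (n_components,)
    total_variance_: float
    boundaries: np.ndarray  # (n_subjects + 1,)
    channel_labels: list[str]

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self.explained_variance_ / self.total_variance_

    def transform(self, data: np.ndarray, whiten: bool = True) -> np.ndarray:
        """Project channels x samples data onto the pooled components."""
        scores = self.components_ @ (data - self.mean_[:, None])
        if whiten:
            scores = scores / np.sqrt(self.explained_variance_)[:, None]
        return scores

    def backproject(self, comp_vectors: np.ndarray, whiten: bool = True) -> np.ndarray:
        """Map vectors in (whitened) component space back to channel space.

        Used to turn SOBI mixing columns into channel topographies.
        """
        if whiten:
            comp_vectors = np.sqrt(self.explained_variance_)[:, None] * comp_vectors
        return self.components_.T @ comp_vectors


def pool_and_reduce(
    recordings: list[EEGRecording], n_components: int, whiten: bool = True
) -> tuple[np.ndarray, PooledPCA]:
    """Concatenate subjects in time and reduce to the top principal components.

    Returns the pooled reduced scores (n_components x total_samples, whitened
    by default) and the fitted :class:`PooledPCA`. The eigendecomposition is
    computed from the pooled channel covariance accumulated subject by
    subject, so no pooled channel-space copy is materialized.
    """
    if not recordings:
        raise ValueError("no recordings to pool")
    labels = recordings[0].channel_labels
    fs = recordings[0].fs
    for rec in recordings[1:]:
        if rec.channel_labels != labels:
            raise ValueError("channel sets differ across subjects")
        if rec.fs != fs:
            raise ValueError("sampling rates differ across subjects")
    n_ch = recordings[0].n_channels
    if not 1 <= n_components <= n_ch:
        raise ValueError(f"n_components must be in [1, {n_ch}]")

    total = sum(r.n_samples for r in recordings)
    mean = np.zeros(n_ch)
    for rec in recordings:
        mean += rec.data.sum(axis=1, dtype=np.float64)
    mean /= total

    cov = np.zeros((n_ch, n_ch))
    for rec in recordings:
        x = rec.data - mean[:, None].astype(rec.data.dtype)
        cov += (x @ x.T).astype(np.float64)
    cov /= total

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.maximum(evals[order], 1e-30)
    components = evecs[:, order].T  # orthonormal rows

    boundaries = np.concatenate([[0], np.cumsum([r.n_samples for r in recordings])])
    pca = PooledPCA(
        components_=components,
        mean_=mean,
        explained_variance_=evals,
        total_variance_=float(np.trace(cov)),
        boundaries=boundaries,
        channel_labels=list(labels),
    )
    scores = np.empty((n_components, total), dtype=np.float32)
    for rec, lo, hi in zip(recordings, boundaries[:-1], boundaries[1:]):
        scores[:, lo:hi] = pca.transform(rec.data, whiten=whiten).astype(np.float32)
    return scores, pca
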