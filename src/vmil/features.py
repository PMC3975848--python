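"""Per-trial spectral features and the behavioural performance series.

Implements the feature side of the decoding pipeline: log-bandpower of each
independent component per trial in five canonical EEG bands (delta, theta,
alpha/mu, beta, gamma), a zero-phase low-pass applied across trials ("trial
domain", one sample per trial), the normalized time-to-target (TTT), and the
TTT periodogram used to choose the trial-domain cut-off c.

The trial-domain cut-off is a normalized angular frequency in radians per
trial: c = 0.1 rad/trial passes only fluctuations slower than about
0.016 cycles per trial (a period of ~63 trials), i.e. the slow learning
trend rather than trial-to-trial jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet, TrialEvents

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "log_bandpower",
    "build_feature_table",
    "trial_domain_lowpass",
    "TTTSeries",
    "normalized_ttt",
    "ttt_psd",
    "zscore",
]

#: power floor (uV^2) added before the log so degenerate epochs stay finite
POWER_FLOOR = 1e-12

#: default trial-domain low-pass cut-off, radians per trial
DEFAULT_CUTOFF = 0.1


@dataclass(frozen=True)
class Band:
    """A named frequency band; edges in Hz, lower inclusive, upper exclusive."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError(f"invalid band edges ({self.lower}, {self.upper})")


DEFAULT_BANDS: dict[str, Band] = {
    b.name: b
    for b in (
        Band("delta", 0.1, 4.0),
        Band("theta", 4.0, 7.0),
        Band("alpha_mu", 8.0, 14.0),
        Band("beta", 20.0, 30.0),
        Band("gamma", 55.0, 85.0),
    )
}


def log_bandpower(
    epoch: np.ndarray, fs: float, band: Band, floor: float = POWER_FLOOR
) -> np.ndarray:
    """Natural-log band power per row of an epoch.

    A Hann window is applied across the full epoch, a single FFT taken, and
    power summed over bins whose center frequency falls in
    ``[band.lower, band.upper)``. Returns ``log(power + floor)``.

    Parameters
    ----------
    epoch : ndarray, shape (..., n_samples)
        One epoch; leading dimensions (channels/components, trials) are kept.
    fs : float
        Sampling rate in Hz.
    band : Band
        Frequency band to integrate.
    floor : float
        Additive power floor keeping the log finite on degenerate input.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    if band.upper > fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.upper} Hz above Nyquist {fs / 2}"
        )
    win = sps.windows.hann(n, sym=False)
    spec = np.fft.rfft(epoch * win, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.lower) & (freqs < band.upper)
    # one-sided power; constant scale factors cancel in any downstream model
    power = (np.abs(spec[..., mask]) ** 2).sum(axis=-1) * (2.0 / (win.sum() ** 2))
    return np.log(power + floor)


def build_feature_table(
    epochs: EpochSet,
    kept_components: np.ndarray | list[int],
    bands: dict[str, Band] | None = None,
    subject: int | None = None,
) -> pd.DataFrame:
    """Trials x (component, band) log-bandpower table.

    Columns are ordered component-major, band-minor, labelled
    ``ic{index:02d}_{band}`` — the fixed, documented order that makes feature
    tables from different subjects line up for cross-subject training.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    kept = np.asarray(kept_components, dtype=int)
    cols: dict[str, np.ndarray] = {}
    for ic in kept:
        series = epochs.epochs[:, ic, :]  # (n_trials, n_samples)
        for name, band in bands.items():
            cols[f"ic{ic:02d}_{name}"] = log_bandpower(series, epochs.fs, band)
    table = pd.DataFrame(cols, index=pd.Index(epochs.trial_indices, name="trial"))
    if subject is not None:
        table.attrs["subject"] = subject
    table.attrs["phase"] = epochs.phase
    return table


def trial_domain_lowpass(
    series: np.ndarray, c: float = DEFAULT_CUTOFF, order: int = 3, axis: int = -1
) -> np.ndarray:
    """Zero-phase low-pass across trials at cut-off ``c`` radians/trial.

    Realized as an order-``order`` Butterworth applied forward-backward
    (``filtfilt``) with reflect padding, so a constant series is returned
    unchanged and no phase shift is introduced. The pad spans roughly one
    period of the cut-off frequency (never less than three times the filter
    order): the filter's transient decays over ~1/c trials, and a shorter
    pad would leak edge transients into short series.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < c < np.pi:
        raise ValueError(f"cut-off must lie in (0, pi) rad/trial, got {c}")
    n = series.shape[axis]
    if n < 20:
        raise ValueError(f"need at least 20 trials for the trial-domain filter, got {n}")
    b, a = sps.butter(order, c / np.pi)
    padlen = min(n - 1, max(3 * order, int(np.ceil(2 * np.pi / c))))
    return sps.filtfilt(b, a, series, axis=axis, padtype="even", padlen=padlen)


@dataclass
class TTTSeries:
    """Normalized time-to-target per trial, raw and trial-domain filtered."""

    raw: np.ndarray  # s/m
    timeout: np.ndarray
    c: float | None = None  # rad/trial used for `filtered`
    filtered: np.ndarray | None = None
    subject: int | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.timeout = np.asarray(self.timeout, dtype=bool)
        if np.any(self.raw < 0):
            raise ValueError("TTT must be non-negative")
        if self.filtered is not None and len(self.filtered) != len(self.raw):
            raise ValueError("filtered and raw TTT must have equal length")

    def __len__(self) -> int:
        return len(self.raw)

    def with_lowpass(self, c: float = DEFAULT_CUTOFF) -> "TTTSeries":
        """Return a copy carrying the trial-domain low-passed series."""
        return TTTSeries(
            raw=self.raw,
            timeout=self.timeout,
            c=c,
            filtered=trial_domain_lowpass(self.raw, c),
            subject=self.subject,
        )


def normalized_ttt(events: TrialEvents, subject: int | None = None) -> TTTSeries:
    """Movement time from go cue to target contact per metre of distance.

    Timeout trials take the full movement time limit and are flagged.
    """
    dist = events.distances
    if np.any(dist <= 0):
        bad = int(np.flatnonzero(dist <= 0)[0])
        raise ValueError(f"zero start-target distance in trial {bad}")
    move = (events.reached_sample - events.go_onset) / events.fs
    move = np.where(events.timeout, events.go_limit, move)
    if np.any(move == 0):
        warnings.warn("trial with zero movement time (reach == go)", stacklevel=2)
    return TTTSeries(raw=move / dist, timeout=events.timeout.copy(), subject=subject)


def ttt_psd(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram of a trial-domain series on a rad/trial grid in [0, pi].

    Used to decide where the informative slow structure of the TTT lives and
    hence to pick the trial-domain cut-off c.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 32:
        raise ValueError("need at least 32 trials for a PSD")
    f, p = sps.periodogram(series, window="boxcar", detrend="constant")
    return 2 * np.pi * f, p


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit variance (population sd)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd
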