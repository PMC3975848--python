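"""Synthetic multi-subject EEG cohorts with a latent motor-learning state.

The generator emulates a 3D reaching study: each subject performs trials
(baseline -> planning -> go -> return) while multi-channel EEG is recorded.
A latent learning state decays exponentially over trials and drives two
observables jointly:

* behaviour — the normalized time-to-target (TTT, seconds per metre of
  start-to-target distance) declines towards an asymptote, plus trial noise;
* physiology — designated cortical sources modulate the amplitude of their
  band-limited oscillation (by default the 8-14 Hz alpha/mu rhythm) as a
  monotone function of the latent state, with configurable sign and strength.

Sources are narrow-band filtered noise on a 1/f background, mixed linearly
into channels (instantaneous ICA model) with additive sensor noise, so the
full decoding pipeline has a ground-truth recovery target: unmixing quality,
feature relevance and prediction significance can all be checked against the
generative configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording, TrialEvents
from .features import DEFAULT_BANDS

__all__ = [
    "LearningCurveSpec",
    "PhaseDurations",
    "SourceCoupling",
    "SimConfig",
    "SyntheticSession",
    "generate_learning_curve",
    "generate_sources",
    "mix_and_record",
    "generate_session",
    "generate_cohort",
]

# stream ids for per-purpose RNG derivation from (seed, subject)
_STREAM_CURVE = 0
_STREAM_EVENTS = 1
_STREAM_SOURCES = 2
_STREAM_MIXING = 3
_STREAM_SENSOR = 4
_STREAM_COHORT = 1000


def _rng(seed: int, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(subject), int(stream)))
    )


@dataclass
class LearningCurveSpec:
    """Three-parameter exponential learning curve for normalized TTT.

    Expected TTT at 0-based trial t is ``asymptote + (initial - asymptote) *
    exp(-t / tau)``; observed TTT adds i.i.d. Gaussian noise, clipped to stay
    positive. Units are s/m.
    """

    initial: float = 40.0
    asymptote: float = 10.0
    tau: float = 50.0  # trials
    noise_sd: float = 3.0

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"decay constant must be positive, got {self.tau}")
        if self.initial <= 0 or self.asymptote <= 0:
            raise ValueError("initial and asymptote TTT must be positive")


@dataclass
class PhaseDurations:
    """Trial phase timing in seconds."""

    baseline: float = 5.0
    planning_min: float = 2.5
    planning_max: float = 4.0
    go_limit: float = 10.0
    return_min: float = 1.0
    return_max: float = 3.0
    inter_trial: float = 0.25
    block_break: float = 60.0


@dataclass
class SourceCoupling:
    """Couples one source's band amplitude to the latent learning state.

    ``strength`` is the slope of log-amplitude in the latent state: the
    per-trial amplitude gain is ``exp(strength * (latent - 0.5))``. A negative
    strength means the band power *rises* as learning proceeds (latent falls),
    i.e. enhanced power goes with better performance.

    The default strength is a calibrated effect size: strong enough that the
    slow component of the coupled bandpower predicts the learning curve
    across subjects, weak enough that single-trial bandpower is noise-
    dominated — the regime in which human trial-to-trial decoding studies
    operate (cross-subject R2_mod roughly 0 to 0.5, not near 1).
    """

    source: int
    band: str = "alpha_mu"
    strength: float = -0.15


@dataclass
class SimConfig:
    """All generative parameters of a synthetic cohort."""

    n_subjects: int = 6
    n_trials: int = 200
    block_size: int = 50
    fs: float = 250.0
    n_channels: int = 32
    n_sources: int = 16
    informative_sources: Sequence[SourceCoupling] = field(
        default_factory=lambda: (SourceCoupling(0), SourceCoupling(1))
    )
    learning_curve: LearningCurveSpec = field(default_factory=LearningCurveSpec)
    phase_durations: PhaseDurations = field(default_factory=PhaseDurations)
    background_exponent: float = 1.0  # 1/f^exponent power spectrum
    background_sd: float = 1.0  # uV
    narrowband_sd: float = 2.0  # uV, rhythmic component at gain 1
    sensor_noise_sd: float = 1.0  # uV
    subject_mixing_jitter: float = 0.05  # relative, per-subject topography wobble
    subject_curve_jitter: float = 0.2  # relative sd on per-subject curve params
    include_artifact: bool = True  # one broadband non-cortical source
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.informative_sources, Sequence):
            self.informative_sources = tuple(
                SourceCoupling(**s) if isinstance(s, dict) else s
                for s in self.informative_sources
            )

    # highest analysis band edge (gamma upper, 85 Hz) sets the Nyquist floor
    _MIN_FS = 170.0

    def validate(self) -> None:
        if self.n_trials % self.block_size != 0:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by block_size={self.block_size}"
            )
        if self.fs < self._MIN_FS:
            raise ValueError(
                f"fs={self.fs} too low: need >= {self._MIN_FS} Hz to cover the "
                "gamma analysis band"
            )
        for c in self.informative_sources:
            if not 0 <= c.source < self.n_sources:
                raise ValueError(f"informative source index {c.source} out of range")
            if c.band not in DEFAULT_BANDS:
                raise ValueError(f"unknown band label {c.band!r}")
        self.learning_curve.validate()

    @property
    def n_sources_total(self) -> int:
        return self.n_sources + int(self.include_artifact)

    @property
    def channel_labels(self) -> list[str]:
        return [f"CH{i + 1:03d}" for i in range(self.n_channels)]


@dataclass
class SyntheticSession:
    """One subject's synthetic recording plus its generative ground truth."""

    subject: int
    eeg: EEGRecording
    events: TrialEvents
    ttt_true: np.ndarray  # s/m, as recoverable from the events
    latent_curve: np.ndarray  # noiseless normalized decay, 1 -> 0
    true_mixing: np.ndarray  # channels x sources (incl. artifact column if any)
    artifact_index: int | None = None  # column of the artifact source, if present

    def __post_init__(self) -> None:
        if len(self.ttt_true) != self.events.n_trials:
            raise ValueError("ttt_true length != trial count")
        if np.any(self.ttt_true <= 0):
            raise ValueError("ttt_true must be strictly positive")
        if self.eeg.n_samples < int(self.events.reached_sample[-1]):
            raise ValueError("EEG shorter than the trial phases it must cover")


def _subject_curve(cfg: SimConfig, subject_index: int) -> LearningCurveSpec:
    """Per-subject learning-curve parameters: lognormal jitter around defaults."""
    base = cfg.learning_curve
    if cfg.subject_curve_jitter == 0:
        return base
    rng = _rng(cfg.seed, subject_index, _STREAM_CURVE)
    j = cfg.subject_curve_jitter
    gain = np.exp(rng.normal(0.0, j, size=3))
    span = (base.initial - base.asymptote) * gain[0]
    asym = base.asymptote * np.exp(rng.normal(0.0, j / 2))
    return LearningCurveSpec(
        initial=asym + span,
        asymptote=asym,
        tau=base.tau * gain[1],
        noise_sd=base.noise_sd * gain[2],
    )


def generate_learning_curve(
    cfg: SimConfig, subject_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial TTT series (with noise) and the noiseless latent state.

    The latent state is the normalized decay ``exp(-t / tau)`` on the 0-based
    trial index: 1 on the first trial, approaching 0. Expected TTT is the
    affine map of the latent state onto [asymptote, initial].
    """
    cfg.validate()
    curve = _subject_curve(cfg, subject_index)
    t = np.arange(cfg.n_trials, dtype=float)
    latent = np.exp(-t / curve.tau)
    expectation = curve.asymptote + (curve.initial - curve.asymptote) * latent
    rng = _rng(cfg.seed, subject_index, _STREAM_CURVE).spawn(1)[0]
    ttt = expectation + rng.normal(0.0, curve.noise_sd, size=cfg.n_trials)
    np.clip(ttt, 1e-3, None, out=ttt)
    return ttt, latent


def _build_events(
    cfg: SimConfig, ttt: np.ndarray, subject_index: int
) -> tuple[TrialEvents, np.ndarray]:
    """Lay out the session timeline; returns events and the realized TTT.

    The realized TTT differs from the requested one only by sample rounding
    and the movement time limit, so ``features.normalized_ttt`` recovers it
    exactly from the events.
    """
    rng = _rng(cfg.seed, subject_index, _STREAM_EVENTS)
    ph = cfg.phase_durations
    fs = cfg.fs
    n = cfg.n_trials

    # endpoint geometry: start at a fixed comfortable position, targets on a
    # per-subject sphere (radius 5-9 cm) with +-10% radial jitter
    start = np.array([0.30, 0.00, 0.20])
    radius = rng.uniform(0.05, 0.09)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = radius * rng.uniform(0.9, 1.1, size=n)
    targets = start + dirs * radii[:, None]
    dist = np.linalg.norm(targets - start, axis=1)

    baseline_onset = np.empty(n, dtype=np.int64)
    planning_onset = np.empty(n, dtype=np.int64)
    go_onset = np.empty(n, dtype=np.int64)
    reached = np.empty(n, dtype=np.int64)
    timeout = np.zeros(n, dtype=bool)

    cursor = int(round(1.0 * fs))  # short lead-in
    for t in range(n):
        if t > 0 and t % cfg.block_size == 0:
            cursor += int(round(ph.block_break * fs))
        baseline_onset[t] = cursor
        planning_onset[t] = cursor + int(round(ph.baseline * fs))
        plan_dur = rng.uniform(ph.planning_min, ph.planning_max)
        go_onset[t] = planning_onset[t] + int(round(plan_dur * fs))
        move_time = ttt[t] * dist[t]
        if move_time >= ph.go_limit:
            timeout[t] = True
            move_time = ph.go_limit
        reached[t] = go_onset[t] + max(1, int(round(move_time * fs)))
        ret = rng.uniform(ph.return_min, ph.return_max)
        cursor = reached[t] + int(round((ret + ph.inter_trial) * fs))

    events = TrialEvents(
        baseline_onset=baseline_onset,
        planning_onset=planning_onset,
        go_onset=go_onset,
        reached_sample=reached,
        timeout=timeout,
        start_pos=np.tile(start, (n, 1)),
        target_pos=targets,
        fs=fs,
        go_limit=ph.go_limit,
    )
    ttt_realized = (reached - go_onset) / fs / dist
    return events, ttt_realized


def _source_spectra(cfg: SimConfig) -> list[tuple[float, float]]:
    """Deterministic (center Hz, half-width Hz) per source.

    Second-order separation can only distinguish sources with distinct
    autocovariances, so every source gets its own spectral line. Informative
    sources sit on evenly spaced slots inside their coupled band; the
    remaining sources are spread over the 4.5-29.5 Hz range (theta through
    beta) on a grid that keeps a guard zone of 1.5 Hz around every
    informative line — near-coincident lines would make the mixture
    unidentifiable in principle, not just hard to estimate.
    """
    spectra: list[tuple[float, float] | None] = [None] * cfg.n_sources
    informative = {c.source: c for c in cfg.informative_sources}
    halfwidth = 0.8
    guard = 1.5
    # informative sources: spread within their own band
    by_band: dict[str, list[int]] = {}
    for idx, c in informative.items():
        by_band.setdefault(c.band, []).append(idx)
    informative_centers: list[float] = []
    for band_name, idxs in by_band.items():
        lo, hi = DEFAULT_BANDS[band_name].lower, DEFAULT_BANDS[band_name].upper
        for k, idx in enumerate(sorted(idxs)):
            center = lo + (k + 1) / (len(idxs) + 1) * (hi - lo)
            spectra[idx] = (center, halfwidth)
            informative_centers.append(center)
    # non-informative: dense candidate grid, keep points clear of the
    # informative lines, pick evenly spaced survivors
    rest = [i for i in range(cfg.n_sources) if spectra[i] is None]
    if rest:
        grid = np.linspace(4.5, min(29.5, cfg.fs / 2 - 2 * halfwidth), 241)
        ok = np.ones(len(grid), dtype=bool)
        for c in informative_centers:
            ok &= np.abs(grid - c) >= guard
        grid = grid[ok]
        picks = grid[np.linspace(0, len(grid) - 1, len(rest)).round().astype(int)]
        for idx, center in zip(rest, picks):
            spectra[idx] = (float(center), halfwidth)
    return spectra  # type: ignore[return-value]


def _narrowband_noise(
    rng: np.random.Generator, n_samples: int, fs: float, center: float, halfwidth: float
) -> np.ndarray:
    lo, hi = center - halfwidth, center + halfwidth
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(f"band edges ({lo:.2f}, {hi:.2f}) Hz outside (0, Nyquist)")
    b, a = sps.butter(4, [lo, hi], btype="bandpass", fs=fs)
    x = sps.lfilter(b, a, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(
    rng: np.random.Generator, n_samples: int, exponent: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    spec = (
        rng.standard_normal(n_samples // 2 + 1)
        + 1j * rng.standard_normal(n_samples // 2 + 1)
    )
    f = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_sources(
    cfg: SimConfig,
    latent: np.ndarray,
    events: TrialEvents,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Source signal matrix (n_sources_total x n_samples).

    Each cortical source is narrow-band noise (its assigned spectral line)
    on a 1/f background. For informative sources the narrow-band amplitude is
    scaled per trial by ``exp(strength * (latent - 0.5))``, constant within a
    trial. The optional artifact source is broadband 40+ Hz noise with no
    trial structure.
    """
    if len(latent) != events.n_trials:
        raise ValueError("latent length must equal the trial count")
    spectra = _source_spectra(cfg)
    informative = {c.source: c for c in cfg.informative_sources}
    out = np.empty((cfg.n_sources_total, n_samples), dtype=np.float32)

    # per-trial gain spans: from this trial's baseline onset to the next one's
    spans = np.concatenate([events.baseline_onset, [n_samples]])
    for i in range(cfg.n_sources):
        center, halfwidth = spectra[i]
        band = _narrowband_noise(rng, n_samples, cfg.fs, center, halfwidth)
        if i in informative and informative[i].strength != 0:
            gain = np.ones(n_samples)
            g_trial = np.exp(informative[i].strength * (latent - 0.5))
            for t in range(events.n_trials):
                gain[spans[t] : spans[t + 1]] = g_trial[t]
            band = band * gain
        bg = _one_over_f_noise(rng, n_samples, cfg.background_exponent)
        out[i] = cfg.narrowband_sd * band + cfg.background_sd * bg

    if cfg.include_artifact:
        hi = min(120.0, cfg.fs / 2 - 1.0)
        b, a = sps.butter(4, [40.0, hi], btype="bandpass", fs=cfg.fs)
        art = sps.lfilter(b, a, rng.standard_normal(n_samples))
        art /= art.std()
        out[-1] = 3.0 * cfg.narrowband_sd * art
    return out


def mix_and_record(
    sources: np.ndarray,
    true_mixing: np.ndarray,
    sensor_noise_sd: float,
    seed: int | np.random.Generator,
    fs: float,
    channel_labels: Sequence[str] | None = None,
) -> EEGRecording:
    """Project sources through the mixing matrix and add i.i.d. sensor noise."""
    true_mixing = np.asarray(true_mixing, dtype=float)
    n_ch, n_src = true_mixing.shape
    if sources.shape[0] != n_src:
        raise ValueError("mixing column count != source count")
    if np.linalg.matrix_rank(true_mixing) < n_src:
        raise ValueError("mixing matrix is rank deficient")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(int(seed))
    )
    data = true_mixing.astype(np.float32) @ sources
    if sensor_noise_sd > 0:
        data += rng.normal(0.0, sensor_noise_sd, size=data.shape).astype(np.float32)
    labels = (
        list(channel_labels)
        if channel_labels is not None
        else [f"CH{i + 1:03d}" for i in range(n_ch)]
    )
    return EEGRecording(data=data, fs=fs, channel_labels=labels, reference="Cz")


def _base_mixing(cfg: SimConfig) -> np.ndarray:
    """Cohort-level mixing topographies (channels x sources), unit columns."""
    rng = _rng(cfg.seed, _STREAM_COHORT, 0)
    A = rng.standard_normal((cfg.n_channels, cfg.n_sources_total))
    if cfg.include_artifact:
        # artifact dominated by a single peripheral channel
        col = np.full(cfg.n_channels, 0.05)
        col *= rng.standard_normal(cfg.n_channels)
        col[0] = 1.0
        A[:, -1] = col
    A /= np.linalg.norm(A, axis=0, keepdims=True)
    return A


def generate_session(cfg: SimConfig, subject_index: int) -> SyntheticSession:
    """One subject's full synthetic session."""
    cfg.validate()
    ttt_req, latent = generate_learning_curve(cfg, subject_index)
    events, ttt = _build_events(cfg, ttt_req, subject_index)
    tail = int(round(2.0 * cfg.fs))
    n_samples = int(events.reached_sample[-1]) + tail

    A = _base_mixing(cfg)
    if cfg.subject_mixing_jitter > 0:
        jrng = _rng(cfg.seed, subject_index, _STREAM_MIXING)
        scale = cfg.subject_mixing_jitter * np.sqrt(np.mean(A[:, : cfg.n_sources] ** 2))
        A = A.copy()
        A[:, : cfg.n_sources] += scale * jrng.standard_normal(
            (cfg.n_channels, cfg.n_sources)
        )

    srng = _rng(cfg.seed, subject_index, _STREAM_SOURCES)
    sources = generate_sources(cfg, latent, events, n_samples, srng)
    nrng = _rng(cfg.seed, subject_index, _STREAM_SENSOR)
    eeg = mix_and_record(
        sources, A, cfg.sensor_noise_sd, nrng, cfg.fs, cfg.channel_labels
    )
    del sources
    return SyntheticSession(
        subject=subject_index,
        eeg=eeg,
        events=events,
        ttt_true=ttt,
        latent_curve=latent,
        true_mixing=A,
        artifact_index=cfg.n_sources_total - 1 if cfg.include_artifact else None,
    )


def generate_cohort(cfg: SimConfig) -> list[SyntheticSession]:
    """All subjects' sessions; deterministic given ``cfg`` (including seed)."""
    cfg.validate()
    if cfg.n_subjects < 1:
        raise ValueError("need at least one subject")
    if cfg.n_subjects < 2:
        warnings.warn("cross-subject validation needs >= 2 subjects", stacklevel=2)
    return [generate_session(cfg, s) for s in range(cfg.n_subjects)]
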