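"""Second-order blind identification (SOBI) by joint diagonalization.

SOBI separates stationary sources with distinct autocorrelation functions:
after whitening, the time-lagged covariance matrices of a linear mixture are
all diagonalized by the same orthogonal matrix, whose columns are the mixing
directions. The joint diagonalizer is found with Jacobi (Givens) rotations
using the closed-form angle of Cardoso & Souloumiac for sets of real
symmetric matrices.

Component order and sign are arbitrary in any ICA; here they are fixed by
convention (decreasing lagged-autocovariance energy; largest-magnitude
topography weight positive) so repeated runs are bit-comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import PooledPCA

__all__ = [
    "lagged_covariances",
    "joint_diagonalize",
    "offdiagonal_criterion",
    "SourceModel",
    "sobi",
    "RejectionCriteria",
    "reject_artifact_ics",
    "amari_index",
    "match_components",
]

DEFAULT_LAGS = tuple(range(1, 51))  # 4-200 ms at 250 Hz


def lagged_covariances(
    signal: np.ndarray, lags: tuple[int, ...] | list[int]
) -> list[np.ndarray]:
    """Symmetrized sample covariances between x(t) and x(t+tau), mean removed.

    Each returned matrix is ``(C + C.T) / 2`` with
    ``C = E[x(t) x(t+tau)^T]``, exactly symmetric by construction.
    """
    x = np.asarray(signal)
    if x.ndim != 2:
        raise ValueError("signal must be 2-D (dims x samples)")
    n = x.shape[1]
    x = x - x.mean(axis=1, keepdims=True)
    out = []
    for tau in lags:
        tau = int(tau)
        if not 0 <= tau < n:
            raise ValueError(f"lag {tau} outside [0, {n})")
        if tau == 0:
            c = (x @ x.T).astype(np.float64) / n
        else:
            c = (x[:, :-tau] @ x[:, tau:].T).astype(np.float64) / (n - tau)
        out.append((c + c.T) / 2.0)
    return out


def offdiagonal_criterion(matrices: list[np.ndarray] | np.ndarray) -> float:
    """Sum of squared off-diagonal entries over a matrix set."""
    m = np.asarray(matrices, dtype=float)
    d = np.eye(m.shape[-1], dtype=bool)
    return float((m[..., ~d] ** 2).sum())


def joint_diagonalize(
    matrices: list[np.ndarray],
    tol: float = 1e-8,
    max_sweeps: int = 200,
    return_info: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Orthogonal joint diagonalizer of a set of symmetric matrices.

    Sweeps Givens rotations over all index pairs; each rotation maximizes the
    summed squared diagonals for its pair (closed-form angle), so the
    off-diagonal criterion never increases. Stops when every rotation angle in
    a sweep has |sin| below ``tol`` or after ``max_sweeps`` sweeps (the latter
    warns rather than fails).

    Returns V with orthonormal columns such that ``V.T @ M @ V`` is as
    diagonal as possible for every M.
    """
    M = np.stack([np.asarray(m, dtype=float) for m in matrices])
    k, n, n2 = M.shape
    if n != n2:
        raise ValueError("matrices must be square")
    if not all(m.shape == (n, n) for m in matrices):
        raise ValueError("matrices must share one dimension")
    V = np.eye(n)
    criterion = [offdiagonal_criterion(M)]
    converged = False
    for sweep in range(max_sweeps):
        max_sin = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                h1 = M[:, p, p] - M[:, q, q]
                h2 = M[:, p, q] + M[:, q, p]
                g11 = h1 @ h1
                g12 = h1 @ h2
                g22 = h2 @ h2
                # principal eigenvector of the 2x2 Gram matrix [[g11,g12],[g12,g22]]
                theta = 0.5 * np.arctan2(2.0 * g12, g11 - g22)
                x = np.cos(theta)
                y = np.sin(theta)
                if x < 0:
                    x, y = -x, -y
                r = np.hypot(x, y)
                c = np.sqrt((x + r) / (2.0 * r))
                s = y / np.sqrt(2.0 * r * (x + r))
                max_sin = max(max_sin, abs(s))
                if abs(s) > tol:
                    cp = M[:, :, p].copy()
                    cq = M[:, :, q].copy()
                    M[:, :, p] = c * cp + s * cq
                    M[:, :, q] = -s * cp + c * cq
                    rp = M[:, p, :].copy()
                    rq = M[:, q, :].copy()
                    M[:, p, :] = c * rp + s * rq
                    M[:, q, :] = -s * rp + c * rq
                    vp = V[:, p].copy()
                    vq = V[:, q].copy()
                    V[:, p] = c * vp + s * vq
                    V[:, q] = -s * vp + c * vq
        criterion.append(offdiagonal_criterion(M))
        if max_sin <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"joint diagonalization did not converge in {max_sweeps} sweeps "
            f"(final off-diagonal criterion {criterion[-1]:.3e})",
            stacklevel=2,
        )
    if return_info:
        return V, {"criterion": np.array(criterion), "converged": converged}
    return V


@dataclass
class SourceModel:
    """Unmixing/mixing in the reduced (whitened PCA) space plus channel
    topographies obtained by PCA back-projection."""

    unmixing: np.ndarray  # (n_components, n_reduced)
    mixing: np.ndarray  # (n_reduced, n_components)
    topographies: np.ndarray  # (n_channels, n_components)
    lags: tuple[int, ...]
    kept_components: np.ndarray = field(default=None)  # type: ignore[assignment]
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kept_components is None:
            self.kept_components = np.arange(self.unmixing.shape[0])
        self.kept_components = np.asarray(self.kept_components, dtype=int)
        if self.topographies.shape[1] != self.unmixing.shape[0]:
            raise ValueError("topography column count != component count")

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def activations(self, reduced_signal: np.ndarray) -> np.ndarray:
        """Apply the unmixing to a reduced-space signal."""
        return self.unmixing @ reduced_signal

    def keep(self, kept: np.ndarray, reasons: dict[int, str]) -> "SourceModel":
        return SourceModel(
            unmixing=self.unmixing,
            mixing=self.mixing,
            topographies=self.topographies,
            lags=self.lags,
            kept_components=np.asarray(kept, dtype=int),
            rejection_reasons=dict(reasons),
        )


def sobi(
    signal: np.ndarray,
    lags: tuple[int, ...] | list[int] = DEFAULT_LAGS,
    tol: float = 1e-8,
    max_sweeps: int = 200,
    pca: PooledPCA | None = None,
) -> tuple[SourceModel, np.ndarray]:
    """Run SOBI on a whitened signal; returns the model and activations.

    The input must be (approximately) whitened: lag-0 covariance close to the
    identity. Components are ordered by decreasing total lagged-autocovariance
    energy and sign-fixed so the largest-magnitude topography weight is
    positive. If ``pca`` is given, topographies are back-projected to the
    original channel space; otherwise they live in the reduced space.
    """
    x = np.asarray(signal)
    c0 = lagged_covariances(x, [0])[0]
    if np.abs(c0 - np.eye(x.shape[0])).max() > 0.2:
        warnings.warn(
            "input does not look whitened (lag-0 covariance far from identity)",
            stacklevel=2,
        )
    covs = lagged_covariances(x, lags)
    V = joint_diagonalize(covs, tol=tol, max_sweeps=max_sweeps)

    # order by total lagged autocovariance energy
    diags = np.stack([np.diag(V.T @ c @ V) for c in covs])  # (n_lags, n)
    energy = (diags**2).sum(axis=0)
    order = np.argsort(energy)[::-1]
    V = V[:, order]

    unmixing = V.T  # components x reduced
    mixing = V  # reduced x components (orthogonal inverse)
    topographies = (
        pca.backproject(mixing, whiten=True) if pca is not None else mixing.copy()
    )
    # sign convention: largest-magnitude topography weight positive
    signs = np.sign(topographies[np.abs(topographies).argmax(axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    unmixing = unmixing * signs[:, None]
    mixing = mixing * signs[None, :]
    topographies = topographies * signs[None, :]

    model = SourceModel(
        unmixing=unmixing,
        mixing=mixing,
        topographies=topographies,
        lags=tuple(int(t) for t in lags),
    )
    return model, model.activations(x)


@dataclass
class RejectionCriteria:
    """Automated stand-in for manual IC inspection.

    A component is rejected if its 3-40 Hz log-log spectral slope falls
    outside ``slope_range`` (EEG spectra fall off roughly like 1/f; a clearly
    positive slope means power rising with frequency, as in EMG), if more
    than ``max_high_freq_fraction`` of its power lies above ``high_freq_hz``
    (broadband muscle/line artifacts), or if a single channel carries more
    than ``max_channel_dominance`` of its squared topography weight (loose
    electrodes, ocular sources near a single sensor). The slope upper bound
    is permissive because band-peaked cortical rhythms (e.g. beta) can have
    a near-zero net slope across 3-40 Hz.
    """

    slope_range: tuple[float, float] = (-8.0, 1.0)
    high_freq_hz: float = 40.0
    max_high_freq_fraction: float = 0.5
    max_channel_dominance: float = 0.8
    slope_band: tuple[float, float] = (3.0, 40.0)


def reject_artifact_ics(
    model: SourceModel,
    activations: np.ndarray,
    fs: float,
    criteria: RejectionCriteria | None = None,
) -> SourceModel:
    """Score each IC's spectrum and topography; return the kept subset."""
    criteria = criteria or RejectionCriteria()
    acts = np.asarray(activations)
    if acts.shape[0] != model.n_components:
        raise ValueError("activation row count != component count")
    # cap the spectral estimate at ~8 minutes of signal for speed
    n_use = min(acts.shape[1], int(fs * 480))
    nper = min(n_use, int(fs * 4))
    f, psd = sps.welch(acts[:, :n_use], fs=fs, nperseg=nper, axis=-1)

    kept, reasons = [], {}
    lo, hi = criteria.slope_band
    fit_mask = (f >= lo) & (f <= hi)
    for i in range(model.n_components):
        p = psd[i]
        hf_frac = p[f > criteria.high_freq_hz].sum() / max(p.sum(), 1e-300)
        slope = np.polyfit(
            np.log10(f[fit_mask]), np.log10(np.maximum(p[fit_mask], 1e-300)), 1
        )[0]
        w2 = model.topographies[:, i] ** 2
        dominance = w2.max() / max(w2.sum(), 1e-300)
        if hf_frac > criteria.max_high_freq_fraction:
            reasons[i] = f"high-frequency power fraction {hf_frac:.2f}"
        elif not criteria.slope_range[0] <= slope <= criteria.slope_range[1]:
            reasons[i] = f"spectral slope {slope:.2f} outside EEG-like range"
        elif dominance > criteria.max_channel_dominance:
            reasons[i] = f"single-channel topography dominance {dominance:.2f}"
        else:
            kept.append(i)
    if not kept:
        raise ValueError("all components rejected as artifacts; pipeline cannot proceed")
    return model.keep(np.array(kept), reasons)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P from a scaled permutation.

    0 means perfect source recovery (P = unmixing @ true mixing is a scaled
    permutation); values stay in [0, 1]-ish with 1-scale meaning no recovery.
    """
    P = np.abs(np.asarray(P, dtype=float))
    n, m = P.shape
    if n != m:
        raise ValueError("Amari index needs a square matrix")
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))


def match_components(
    topographies: np.ndarray, true_mixing: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy match of estimated components to true sources by |cosine|.

    Returns (component index per true source, cosine similarity per source).
    """
    T = topographies / np.linalg.norm(topographies, axis=0, keepdims=True)
    A = true_mixing / np.linalg.norm(true_mixing, axis=0, keepdims=True)
    sim = np.abs(T.T @ A)  # (n_components, n_sources)
    match = np.full(A.shape[1], -1, dtype=int)
    score = np.zeros(A.shape[1])
    taken: set[int] = set()
    for _ in range(A.shape[1]):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        match[j] = i
        score[j] = sim[i, j]
        sim[i, :] = -1
        sim[:, j] = -1
        taken.add(int(i))
    return match, score
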