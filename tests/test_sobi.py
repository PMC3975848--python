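"""SOBI tests: lagged covariances, Jacobi joint diagonalization against
closed-form/eigendecomposition oracles, source recovery and IC rejection."""

import numpy as np
import pytest
from scipy import signal as sps

from vmil.sobi import (
    RejectionCriteria,
    SourceModel,
    amari_index,
    joint_diagonalize,
    lagged_covariances,
    match_components,
    offdiagonal_criterion,
    reject_artifact_ics,
    sobi,
)


def _ar(coeffs, n, rng, burn=500):
    """AR process x_t = sum_k coeffs[k] x_{t-1-k} + e_t."""
    e = rng.standard_normal(n + burn)
    x = sps.lfilter([1.0], np.r_[1.0, -np.asarray(coeffs)], e)
    return x[burn:]


class TestLaggedCovariances:
    def test_white_noise_lagged_covariance_vanishes(self, rng):
        x = rng.standard_normal((4, 40000))
        c = lagged_covariances(x, [5])[0]
        assert np.abs(c).max() < 3.0 / np.sqrt(x.shape[1])

    def test_lag_zero_of_whitened_input_is_identity(self, rng):
        x = rng.standard_normal((3, 20000))
        x = np.linalg.cholesky(np.linalg.inv(np.cov(x))).T @ (x - x.mean(1, keepdims=True))
        c = lagged_covariances(x, [0])[0]
        np.testing.assert_allclose(c, np.eye(3), atol=0.05)

    def test_ar1_autocovariance_matches_phi_times_variance(self, rng):
        """AR(1) oracle: cov(x_t, x_{t+1}) = phi * var(x)."""
        phi = 0.6
        x = _ar([phi], 200000, rng)[None, :]
        c0 = lagged_covariances(x, [0])[0][0, 0]
        c1 = lagged_covariances(x, [1])[0][0, 0]
        assert c1 / c0 == pytest.approx(phi, abs=0.02)

    def test_matrices_symmetric_and_lag_validated(self, rng):
        x = rng.standard_normal((3, 1000))
        for c in lagged_covariances(x, [1, 7, 30]):
            np.testing.assert_array_equal(c, c.T)
        with pytest.raises(ValueError, match="lag"):
            lagged_covariances(x, [1000])


def _rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _perm_sign_close(V, U, atol=0.05):
    """True if V equals U up to column permutation and sign."""
    M = np.abs(V.T @ U)
    return np.allclose(np.sort(M.max(axis=0)), 1.0, atol=atol) and np.allclose(
        np.sort(M.max(axis=1)), 1.0, atol=atol
    )


class TestJointDiagonalize:
    def test_already_diagonal_set_gives_identity_like_rotation(self):
        mats = [np.diag([3.0, 1.0, 0.2]), np.diag([0.5, 2.0, 1.0])]
        V = joint_diagonalize(mats)
        assert _perm_sign_close(V, np.eye(3), atol=1e-8)

    def test_commuting_set_matches_eigenvector_oracle(self, rng):
        """Matrices sharing eigenvectors: the joint diagonalizer must match
        the eigendecomposition (up to permutation/sign)."""
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        mats = [Q @ np.diag(rng.uniform(0.5, 3.0, 5)) @ Q.T for _ in range(4)]
        V = joint_diagonalize(mats)
        assert _perm_sign_close(V, Q)

    def test_recovers_known_rotation_angle(self):
        """Two 2x2 matrices diagonalized by a 30-degree rotation; oracle is a
        1-D grid search over the rotation angle."""
        theta = np.deg2rad(30.0)
        R = _rotation(theta)
        mats = [R @ np.diag([2.0, 0.5]) @ R.T, R @ np.diag([0.3, 1.7]) @ R.T]

        def offdiag_at(angle):
            G = _rotation(angle)
            return sum((G.T @ m @ G)[0, 1] ** 2 for m in mats)

        grid = np.linspace(-np.pi / 2, np.pi / 2, 100001)
        oracle = grid[np.argmin([offdiag_at(a) for a in grid])]
        V = joint_diagonalize(mats, tol=1e-12)
        got = np.arctan2(V[1, 0], V[0, 0])
        # compare modulo the 90-degree permutation ambiguity
        # oracle precision is limited by its grid spacing (~3e-5 rad)
        diff = (got - oracle + np.pi / 4) % (np.pi / 2) - np.pi / 4
        assert abs(diff) < 5e-5
        assert abs((got - theta + np.pi / 4) % (np.pi / 2) - np.pi / 4) < 1e-9

    def test_offdiagonal_criterion_non_increasing(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        mats = [
            Q @ np.diag(rng.uniform(0.1, 2.0, 6)) @ Q.T
            + 0.05 * _sym(rng.standard_normal((6, 6)))
            for _ in range(5)
        ]
        _, info = joint_diagonalize(mats, return_info=True)
        crit = info["criterion"]
        assert np.all(np.diff(crit) <= 1e-10)
        assert info["converged"]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_diagonalize([np.eye(3), np.eye(4)])


def _sym(a):
    return (a + a.T) / 2


class TestSobi:
    def _whiten(self, x):
        c = np.cov(x)
        evals, evecs = np.linalg.eigh(c)
        return (evecs / np.sqrt(evals)).T @ (x - x.mean(1, keepdims=True))

    def test_recovers_orthogonal_mixture_of_ar2_sources(self, rng):
        """Two AR(2) sources with distinct resonances, orthogonally mixed:
        Amari index of (unmixing @ mixing) below 0.1."""
        n = 60000
        s = np.vstack(
            [
                _ar([1.6, -0.9], n, rng),  # resonance ~ slow
                _ar([0.2, -0.8], n, rng),  # resonance ~ fast
            ]
        )
        Q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        x = self._whiten(Q @ s)
        model, acts = sobi(x, lags=tuple(range(1, 21)))
        # total channel-space transform vs the effective mixing after whitening
        P = model.unmixing @ self._whiten_mat(Q @ s) @ Q
        assert amari_index(P) < 0.1
        assert acts.shape == x.shape

    def _whiten_mat(self, x):
        c = np.cov(x)
        evals, evecs = np.linalg.eigh(c)
        return (evecs / np.sqrt(evals)).T

    def test_channel_permutation_equivariance(self, rng):
        n = 20000
        s = np.vstack([_ar([0.9], n, rng), _ar([-0.5], n, rng), _ar([0.3], n, rng)])
        x = self._whiten(s)
        perm = [2, 0, 1]
        m1, _ = sobi(x, lags=(1, 2, 3, 5))
        m2, _ = sobi(x[perm], lags=(1, 2, 3, 5))
        # topographies (reduced space here) permute their rows accordingly
        assert _perm_sign_close_cols(m2.topographies[np.argsort(perm)], m1.topographies)

    def test_time_reversal_invariance(self, rng):
        n = 40000
        s = np.vstack([_ar([1.2, -0.6], n, rng), _ar([-0.4], n, rng)])
        x = self._whiten(s)
        m1, _ = sobi(x, lags=tuple(range(1, 11)))
        m2, _ = sobi(x[:, ::-1].copy(), lags=tuple(range(1, 11)))
        assert amari_index(m1.unmixing @ np.linalg.pinv(m2.unmixing)) < 0.05


def _perm_sign_close_cols(A, B, atol=0.05):
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    M = np.abs(An.T @ Bn)
    return np.allclose(np.sort(M.max(axis=0)), 1.0, atol=atol)


class TestRejection:
    def _model(self, topographies, lags=(1, 2)):
        n = topographies.shape[1]
        return SourceModel(
            unmixing=np.eye(n),
            mixing=np.eye(n),
            topographies=topographies,
            lags=lags,
        )

    def test_broadband_high_frequency_component_rejected(self, rng):
        fs = 250.0
        n = int(fs * 60)
        b, a = sps.butter(4, [50.0, 90.0], btype="bandpass", fs=fs)
        hf = sps.lfilter(b, a, rng.standard_normal(n))
        alpha = sps.lfilter(*sps.butter(4, [9.0, 11.0], btype="bandpass", fs=fs),
                            rng.standard_normal(n))
        alpha = alpha / alpha.std() + 0.2 * rng.standard_normal(n)
        acts = np.vstack([alpha, hf])
        topo = rng.standard_normal((8, 2))
        model = reject_artifact_ics(self._model(topo), acts, fs)
        assert list(model.kept_components) == [0]
        assert "high-frequency" in model.rejection_reasons[1]

    def test_single_channel_dominated_component_rejected(self, rng):
        fs = 250.0
        n = int(fs * 60)
        alpha = sps.lfilter(*sps.butter(4, [9.0, 11.0], btype="bandpass", fs=fs),
                            rng.standard_normal((2, n)), axis=-1)
        topo = np.full((10, 2), 0.3)
        topo[0, 1] = 10.0  # second component lives on one channel
        model = reject_artifact_ics(self._model(topo), alpha, fs)
        assert list(model.kept_components) == [0]
        assert "dominance" in model.rejection_reasons[1]

    def test_all_artifacts_is_an_error(self, rng):
        fs = 250.0
        n = int(fs * 30)
        b, a = sps.butter(4, [60.0, 100.0], btype="bandpass", fs=fs)
        acts = sps.lfilter(b, a, rng.standard_normal((2, n)), axis=-1)
        with pytest.raises(ValueError, match="all components rejected"):
            reject_artifact_ics(self._model(np.ones((4, 2))), acts, fs)


class TestAmariAndMatching:
    def test_scaled_permutation_scores_zero(self, rng):
        P = np.zeros((4, 4))
        for i, j in enumerate([2, 0, 3, 1]):
            P[i, j] = rng.uniform(0.5, 2.0) * (-1) ** i
        assert amari_index(P) == pytest.approx(0.0, abs=1e-12)

    def test_random_matrix_scores_high(self, rng):
        P = rng.standard_normal((6, 6))
        assert amari_index(P) > 0.3

    def test_match_components_identifies_true_sources(self, rng):
        A = rng.standard_normal((12, 4))
        perm = [3, 1, 0, 2]
        topo = A[:, perm] * np.array([1, -1, 1, -1])
        match, score = match_components(topo, A)
        assert [perm.index(j) for j in range(4)] == list(match)
        np.testing.assert_allclose(score, 1.0, atol=1e-12)
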