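"""Feature tests: log-bandpower, feature tables, trial-domain filtering,
normalized TTT and its periodogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vmil.containers import EpochSet
from vmil.features import (
    DEFAULT_BANDS,
    POWER_FLOOR,
    Band,
    build_feature_table,
    log_bandpower,
    normalized_ttt,
    trial_domain_lowpass,
    ttt_psd,
    zscore,
)


class TestLogBandpower:
    def test_pure_tone_concentrates_in_its_band(self):
        fs, n = 250.0, 1250
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        a = log_bandpower(x, fs, DEFAULT_BANDS["alpha_mu"])
        b = log_bandpower(x, fs, DEFAULT_BANDS["beta"])
        assert a - b > 3.0

    def test_white_noise_band_ratio_follows_bandwidth(self, rng):
        """alpha/mu (6 Hz) vs theta (3 Hz): mean linear power ratio ~ 2."""
        fs, n = 250.0, 625
        x = rng.standard_normal((1000, n))
        pa = np.exp(log_bandpower(x, fs, DEFAULT_BANDS["alpha_mu"]))
        pt = np.exp(log_bandpower(x, fs, DEFAULT_BANDS["theta"]))
        assert pa.mean() / pt.mean() == pytest.approx(2.0, rel=0.1)

    def test_zero_signal_hits_documented_floor(self):
        out = log_bandpower(np.zeros(500), 250.0, DEFAULT_BANDS["alpha_mu"])
        assert np.isfinite(out)
        assert out == pytest.approx(np.log(POWER_FLOOR))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            log_bandpower(np.ones(100), 100.0, DEFAULT_BANDS["gamma"])

    def test_default_band_edges(self):
        edges = {k: (b.lower, b.upper) for k, b in DEFAULT_BANDS.items()}
        assert edges == {
            "delta": (0.1, 4.0),
            "theta": (4.0, 7.0),
            "alpha_mu": (8.0, 14.0),
            "beta": (20.0, 30.0),
            "gamma": (55.0, 85.0),
        }


def _epochs(n_trials, n_ics, n_samp=625, fs=250.0, seed=0):
    rng = np.random.default_rng(seed)
    return EpochSet(
        epochs=rng.standard_normal((n_trials, n_ics, n_samp)),
        phase="planning",
        fs=fs,
    )


class TestFeatureTable:
    @pytest.mark.parametrize("n_ics,expected", [(14, 70), (10, 50)])
    def test_column_count_is_ics_times_bands(self, n_ics, expected):
        table = build_feature_table(_epochs(8, n_ics), np.arange(n_ics))
        assert table.shape == (8, expected)

    def test_column_order_ic_major_band_minor(self):
        table = build_feature_table(_epochs(3, 4), [1, 3])
        bands = list(DEFAULT_BANDS)
        assert list(table.columns) == [
            f"ic{ic:02d}_{b}" for ic in (1, 3) for b in bands
        ]

    def test_row_per_trial_and_finite(self):
        table = build_feature_table(_epochs(200, 3), [0, 1, 2])
        assert len(table) == 200
        assert np.isfinite(table.to_numpy()).all()


class TestTrialLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(80, 3.7)
        np.testing.assert_allclose(trial_domain_lowpass(x, 0.1), x, atol=1e-9)

    def test_alternating_series_strongly_attenuated(self):
        x = np.resize([1.0, -1.0], 200)
        out = trial_domain_lowpass(x, 0.1)
        assert np.abs(out).max() < 0.05

    def test_deep_passband_sinusoid_preserved(self):
        t = np.arange(600)
        x = np.sin(0.02 * t)
        out = trial_domain_lowpass(x, 0.1)
        mid = slice(100, 500)
        amp = np.abs(out[mid]).max()
        assert amp == pytest.approx(np.abs(x[mid]).max(), rel=0.05)

    def test_cutoff_domain_validated(self):
        x = np.zeros(50)
        for bad in (0.0, -0.1, np.pi, 4.0):
            with pytest.raises(ValueError, match="cut-off"):
                trial_domain_lowpass(x, bad)
        with pytest.raises(ValueError, match="20 trials"):
            trial_domain_lowpass(np.zeros(10), 0.1)

    @given(
        a=st.floats(-3, 3),
        b=st.floats(-3, 3),
    )
    def test_linearity(self, a, b):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 60))
        lhs = trial_domain_lowpass(a * x + b * y, 0.1)
        rhs = a * trial_domain_lowpass(x, 0.1) + b * trial_domain_lowpass(y, 0.1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_idempotent_in_deep_passband(self):
        t = np.arange(600)
        x = np.sin(0.01 * t)
        once = trial_domain_lowpass(x, 0.1)
        twice = trial_domain_lowpass(once, 0.1)
        np.testing.assert_allclose(twice[100:500], once[100:500], atol=0.02)


class TestNormalizedTTT:
    def test_arithmetic(self, tiny_session):
        """5 s movement over 0.25 m is 20 s/m, and the generator's events
        reproduce its ground-truth TTT exactly."""
        ev = tiny_session.events
        ttt = normalized_ttt(ev)
        np.testing.assert_allclose(ttt.raw, tiny_session.ttt_true, rtol=1e-12)
        # direct arithmetic check on one trial
        t = 4
        move = (ev.reached_sample[t] - ev.go_onset[t]) / ev.fs
        assert ttt.raw[t] == pytest.approx(move / ev.distances[t])

    def test_timeout_trial_uses_limit_and_flags(self, tiny_session):
        ev = tiny_session.events
        timeout = ev.timeout.copy()
        timeout[3] = True
        ev2 = type(ev)(
            baseline_onset=ev.baseline_onset,
            planning_onset=ev.planning_onset,
            go_onset=ev.go_onset,
            reached_sample=ev.reached_sample,
            timeout=timeout,
            start_pos=ev.start_pos,
            target_pos=ev.target_pos,
            fs=ev.fs,
            go_limit=10.0,
        )
        ttt = normalized_ttt(ev2)
        assert ttt.timeout[3]
        assert ttt.raw[3] == pytest.approx(10.0 / ev.distances[3])

    def test_zero_distance_rejected(self, tiny_session):
        ev = tiny_session.events
        target = ev.target_pos.copy()
        target[0] = ev.start_pos[0]
        bad = type(ev)(
            baseline_onset=ev.baseline_onset,
            planning_onset=ev.planning_onset,
            go_onset=ev.go_onset,
            reached_sample=ev.reached_sample,
            timeout=ev.timeout,
            start_pos=ev.start_pos,
            target_pos=target,
            fs=ev.fs,
        )
        with pytest.raises(ValueError, match="distance"):
            normalized_ttt(bad)


class TestTTTPsd:
    def test_slow_decay_energy_below_cutoff(self):
        # periodogram of the closed-form learning curve: >=80% of the energy
        # of a tau=50 exponential over 400 trials lies below 0.1 rad/trial
        t = np.arange(400)
        x = 30 * np.exp(-t / 50.0)
        w, p = ttt_psd(x)
        assert p[w < 0.1].sum() / p.sum() > 0.8

    def test_sinusoid_peak_located(self):
        t = np.arange(256)
        x = np.sin(0.5 * t)
        w, p = ttt_psd(x)
        assert w[np.argmax(p)] == pytest.approx(0.5, abs=0.03)

    def test_white_noise_spectrum_spread_out(self, rng):
        w, p = ttt_psd(rng.standard_normal(512))
        assert p[w < 0.1].sum() / p.sum() < 0.15

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError, match="32"):
            ttt_psd(np.zeros(16))


def test_zscore_standardizes_and_rejects_constant():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    z = zscore(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        zscore(np.ones(5))
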