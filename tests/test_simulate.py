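"""Generator tests: learning curve, source coupling, mixing, cohort
reproducibility."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vmil.containers import TrialEvents
from vmil.features import DEFAULT_BANDS, log_bandpower
from vmil.simulate import (
    LearningCurveSpec,
    SimConfig,
    SourceCoupling,
    generate_cohort,
    generate_learning_curve,
    generate_sources,
    mix_and_record,
)

from conftest import tiny_config


def _noiseless(**kw):
    return tiny_config(
        subject_curve_jitter=0.0,
        learning_curve=LearningCurveSpec(noise_sd=0.0, **kw),
    )


class TestLearningCurve:
    def test_closed_form_value_at_one_decay_constant(self):
        """initial 40, asymptote 10, tau 50 -> 10 + 30/e at trial index 50."""
        cfg = tiny_config(
            n_trials=60,
            subject_curve_jitter=0.0,
            learning_curve=LearningCurveSpec(40.0, 10.0, 50.0, 0.0),
        )
        ttt, latent = generate_learning_curve(cfg, 0)
        assert ttt[0] == pytest.approx(40.0)
        assert ttt[50] == pytest.approx(10.0 + 30.0 * np.exp(-1.0), rel=1e-12)
        assert latent[0] == 1.0

    def test_noiseless_curve_strictly_decreasing_to_asymptote(self):
        cfg = _noiseless(initial=30.0, asymptote=12.0, tau=8.0)
        ttt, latent = generate_learning_curve(cfg, 0)
        assert np.all(np.diff(ttt) < 0)
        assert ttt[-1] == pytest.approx(12.0, abs=0.3)
        assert np.all(latent > 0) and latent[-1] < 0.01

    def test_infinite_decay_constant_gives_constant_series(self):
        cfg = _noiseless(initial=25.0, asymptote=10.0, tau=1e12)
        ttt, _ = generate_learning_curve(cfg, 0)
        np.testing.assert_allclose(ttt, 25.0, rtol=1e-9)

    def test_noise_is_zero_mean_around_expectation(self):
        cfg = tiny_config(n_trials=200, block_size=50, subject_curve_jitter=0.0)
        ttt, latent = generate_learning_curve(cfg, 0)
        lc = cfg.learning_curve
        expect = lc.asymptote + (lc.initial - lc.asymptote) * latent
        resid = ttt - expect
        assert abs(resid.mean()) < 3 * lc.noise_sd / np.sqrt(200)
        assert np.all(ttt > 0)

    def test_non_positive_decay_constant_rejected(self):
        cfg = tiny_config(learning_curve=LearningCurveSpec(tau=-1.0))
        with pytest.raises(ValueError, match="decay"):
            generate_learning_curve(cfg, 0)


def _step_events(n_trials: int, fs: float, trial_sec: float = 4.0) -> TrialEvents:
    """Back-to-back trials of fixed length, for direct source-level checks."""
    span = int(trial_sec * fs)
    base = np.arange(n_trials) * span
    return TrialEvents(
        baseline_onset=base,
        planning_onset=base + span // 4,
        go_onset=base + span // 2,
        reached_sample=base + 3 * span // 4,
        timeout=np.zeros(n_trials, bool),
        start_pos=np.zeros((n_trials, 3)),
        target_pos=np.tile([0.1, 0, 0], (n_trials, 1)),
        fs=fs,
    )


def _trial_bandpower(sources, events, fs, source, band, n_samp):
    idx = events.baseline_onset[:, None] + np.arange(n_samp)[None, :]
    return log_bandpower(sources[source][idx], fs, DEFAULT_BANDS[band])


class TestSources:
    def test_zero_coupling_removes_trial_structure(self, rng):
        cfg = tiny_config(informative_sources=(SourceCoupling(0, strength=0.0),))
        n, fs = 60, cfg.fs
        events = _step_events(n, fs)
        latent = np.exp(-np.arange(n) / 20)
        S = generate_sources(cfg, latent, events, int(events.reached_sample[-1] + fs), rng)
        bp = _trial_bandpower(S, events, fs, 0, "alpha_mu", int(2 * fs))
        rho = spearmanr(bp, latent).statistic
        assert abs(rho) < 0.35  # no systematic effect beyond sampling noise

    def test_step_latent_shifts_bandpower_over_50_trial_averages(self, rng):
        """Positive coupling, latent 1 vs 0: higher alpha/mu power at 1."""
        cfg = tiny_config(informative_sources=(SourceCoupling(0, strength=0.8),))
        n, fs = 100, cfg.fs
        events = _step_events(n, fs)
        latent = np.concatenate([np.ones(50), np.zeros(50)])
        S = generate_sources(cfg, latent, events, int(events.reached_sample[-1] + fs), rng)
        bp = _trial_bandpower(S, events, fs, 0, "alpha_mu", int(2 * fs))
        # expected log-power separation ~= 2 * strength = 1.6
        assert bp[:50].mean() - bp[50:].mean() > 0.8

    def test_disjoint_band_sources_uncorrelated(self, rng):
        cfg = tiny_config()
        n, fs = 20, cfg.fs
        events = _step_events(n, fs, trial_sec=3.0)
        latent = np.ones(n)
        n_samp = int(events.reached_sample[-1] + fs)
        S = generate_sources(cfg, latent, events, n_samp, rng)
        # sources 1 (theta) and 3 (beta) occupy disjoint bands
        r = np.corrcoef(S[1], S[3])[0, 1]
        assert abs(r) < 0.1

    def test_monotone_coupling_sign_and_strength(self, rng):
        """Spearman(log-bandpower, latent) carries the configured sign; at
        strong coupling the association is strong."""
        n = 200
        latent = np.exp(-np.arange(n) / 50)
        for strength, bound in ((-0.8, -0.5), (-0.15, 0.0)):
            cfg = tiny_config(
                n_trials=n,
                block_size=50,
                informative_sources=(SourceCoupling(0, strength=strength),),
            )
            events = _step_events(n, cfg.fs, trial_sec=6.0)
            S = generate_sources(
                cfg, latent, events, int(events.reached_sample[-1] + cfg.fs), rng
            )
            bp = _trial_bandpower(S, events, cfg.fs, 0, "alpha_mu", int(5 * cfg.fs))
            rho = spearmanr(bp, latent).statistic
            assert rho < bound

    def test_band_outside_nyquist_rejected(self, rng):
        # at fs 130 the gamma-band source (center ~70 Hz) exceeds Nyquist
        cfg = tiny_config(
            fs=130.0, informative_sources=(SourceCoupling(0, band="gamma"),)
        )
        events = _step_events(4, cfg.fs)
        with pytest.raises(ValueError, match="Nyquist|edges"):
            generate_sources(
                cfg, np.ones(4), events, int(events.reached_sample[-1] + cfg.fs), rng
            )


class TestMixing:
    def test_identity_mixing_zero_noise_returns_sources(self, rng):
        S = rng.standard_normal((4, 1000)).astype(np.float32)
        rec = mix_and_record(S, np.eye(4), 0.0, 0, fs=250.0)
        np.testing.assert_allclose(rec.data, S, atol=1e-6)

    def test_zero_sources_yield_pure_sensor_noise(self):
        S = np.zeros((3, 20000), dtype=np.float32)
        rec = mix_and_record(S, np.eye(4, 3), 1.5, 11, fs=250.0)
        assert rec.data.std() == pytest.approx(1.5, rel=0.05)

    def test_same_seed_bit_identical(self, rng):
        S = rng.standard_normal((3, 500)).astype(np.float32)
        A = rng.standard_normal((6, 3))
        r1 = mix_and_record(S, A, 1.0, 99, fs=250.0)
        r2 = mix_and_record(S, A, 1.0, 99, fs=250.0)
        assert np.array_equal(r1.data, r2.data)

    def test_rank_deficient_mixing_rejected(self, rng):
        S = rng.standard_normal((3, 500)).astype(np.float32)
        A = np.ones((6, 3))
        with pytest.raises(ValueError, match="rank"):
            mix_and_record(S, A, 1.0, 0, fs=250.0)


class TestCohort:
    def test_default_config_matches_study_conditions(self):
        cfg = SimConfig()
        assert cfg.n_subjects == 6
        assert cfg.n_trials == 200 and cfg.block_size == 50

    def test_cohort_shape_and_event_counts(self, tiny_cohort):
        cfg = tiny_config()
        assert len(tiny_cohort) == cfg.n_subjects
        for sess in tiny_cohort:
            assert sess.events.n_trials == cfg.n_trials
            assert len(sess.ttt_true) == cfg.n_trials
            assert np.all(sess.ttt_true > 0)
            assert sess.eeg.n_samples >= sess.events.reached_sample[-1]

    def test_reproducible_given_config(self):
        cfg = tiny_config(n_trials=20, block_size=10, n_subjects=2)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(tiny_config(n_trials=20, block_size=10, n_subjects=2))
        for a, b in zip(c1, c2):
            assert np.array_equal(a.eeg.data, b.eeg.data)
            assert np.array_equal(a.ttt_true, b.ttt_true)

    def test_zero_perturbation_shares_topographies(self):
        cfg = tiny_config(
            n_trials=20, block_size=10, n_subjects=2, subject_mixing_jitter=0.0
        )
        c = generate_cohort(cfg)
        np.testing.assert_array_equal(c[0].true_mixing, c[1].true_mixing)

    def test_subjects_have_distinct_noise(self, tiny_cohort):
        a, b = tiny_cohort[0], tiny_cohort[1]
        n = min(a.eeg.n_samples, b.eeg.n_samples)
        assert not np.array_equal(a.eeg.data[:, :n], b.eeg.data[:, :n])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SimConfig(n_trials=190, block_size=50).validate()
        with pytest.raises(ValueError, match="fs"):
            SimConfig(fs=100.0).validate()
        with pytest.raises(ValueError, match="out of range"):
            SimConfig(
                n_sources=4, informative_sources=(SourceCoupling(9),)
            ).validate()
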