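"""Null calibration of the group permutation test.

Under a coupling of zero the EEG carries no information about the learning
state, and per-trial log-bandpower of each independent component reduces to
i.i.d. estimation noise across trials (trials are disjoint windows of a
trial-stationary source). This module exploits that reduction to check the
permutation test's false-positive rate at the *feature level*: each
replicate draws per-subject TTT learning curves and feature tables of pure
noise, pushes them through the identical trial-domain filtering, LOSO
forest and permutation test as the full pipeline, and records the p-value.

With a calibrated test the rejection rate at level alpha stays inside the
binomial confidence band around alpha. Running the EEG stages (mixing,
PCA, SOBI) for every replicate would only interpose invertible linear maps
between the noise and the features, so they are omitted here for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import group_permutation_test
from .features import DEFAULT_CUTOFF
from .model import ForestSpec, TTTDecoder
from .simulate import SimConfig, generate_learning_curve

__all__ = ["CalibrationConfig", "null_calibration", "rejection_rate_ci"]


@dataclass
class CalibrationConfig:
    """Shape of one null replicate.

    The cohort geometry follows the default study conditions (6 subjects,
    200 trials); the forest is thinned (fewer trees, fewer feature columns)
    because the null distribution of the test statistic does not depend on
    ensemble size, only on the smoothness of predictions — which the
    trial-domain filter, not the forest, controls.
    """

    n_subjects: int = 6
    n_trials: int = 200
    n_features: int = 20
    feature_noise_sd: float = 0.45  # log-power units, per-trial estimation noise
    c: float = DEFAULT_CUTOFF
    n_perm: int = 300
    forest: ForestSpec = field(
        default_factory=lambda: ForestSpec(n_trees=60, min_leaf=5)
    )
    aggregate: str = "mean"
    recompute_denominator: bool = False
    #: diagnostic switch: skip the trial-domain low-pass of the features, so
    #: null predictions are white across trials (see module notes on
    #: exchangeability)
    filter_features: bool = True


def _null_replicate(
    cfg: CalibrationConfig, sim: SimConfig, rep_seed: int
) -> float:
    """One coupling-free cohort -> permutation-test p-value."""
    rng = np.random.default_rng(rep_seed)
    sim = SimConfig(
        n_subjects=cfg.n_subjects,
        n_trials=cfg.n_trials,
        block_size=sim.block_size,
        learning_curve=sim.learning_curve,
        subject_curve_jitter=sim.subject_curve_jitter,
        informative_sources=(),
        seed=int(rng.integers(2**31)),
    )
    tables, ttts = [], []
    cols = [f"f{j:02d}" for j in range(cfg.n_features)]
    for s in range(cfg.n_subjects):
        ttt, _ = generate_learning_curve(sim, s)
        ttts.append(ttt)
        noise = rng.normal(0.0, cfg.feature_noise_sd, (cfg.n_trials, cfg.n_features))
        tables.append(pd.DataFrame(noise, columns=cols))
    spec = ForestSpec(
        n_trees=cfg.forest.n_trees,
        max_features=cfg.forest.max_features,
        min_leaf=cfg.forest.min_leaf,
        bootstrap=cfg.forest.bootstrap,
        seed=int(rng.integers(2**31)),
    )
    decoder = TTTDecoder(
        tables, ttts, spec=spec, c=cfg.c, filter_features=cfg.filter_features
    )
    res = decoder.fit()
    outcome = group_permutation_test(
        list(zip(res.actual, res.predicted)),
        c=cfg.c,
        n_perm=cfg.n_perm,
        seed=int(rng.integers(2**31)),
        aggregate=cfg.aggregate,
        recompute_denominator=cfg.recompute_denominator,
    )
    return outcome.p_value


def null_calibration(
    n_replicates: int = 100,
    seed: int = 0,
    cfg: CalibrationConfig | None = None,
    sim: SimConfig | None = None,
) -> np.ndarray:
    """p-values from ``n_replicates`` independent coupling-free cohorts."""
    cfg = cfg or CalibrationConfig()
    sim = sim or SimConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    return np.array([_null_replicate(cfg, sim, int(s)) for s in seeds])


def rejection_rate_ci(
    n_replicates: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Normal-approximation 95% CI for the rejection rate of a calibrated
    test at level ``alpha`` over ``n_replicates`` runs."""
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_replicates)
    return max(alpha - half, 0.0), alpha + half
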