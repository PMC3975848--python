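"""Shared fixtures: a desk-scale cohort for unit tests and one full
default-conditions pipeline run reused by the acceptance-level tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vmil.pipeline import PipelineConfig, run
from vmil.simulate import PhaseDurations, SimConfig, SourceCoupling, generate_cohort

settings.register_profile(
    "vmil",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vmil")


def tiny_config(**overrides) -> SimConfig:
    """Small, fast cohort: 3 subjects x 40 trials, 12 channels, 6 sources.

    Couplings are strong so effects are detectable at this scale.
    """
    defaults = dict(
        n_subjects=3,
        n_trials=40,
        block_size=20,
        n_channels=12,
        n_sources=6,
        informative_sources=(SourceCoupling(0, strength=-0.8),),
        phase_durations=PhaseDurations(block_break=5.0),
        seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_session(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline under the default study conditions (6 subjects x 200
    trials, 250 Hz, 32 channels, coupling on), planning phase, 10,000
    permutations. Shared across tests because it is the expensive fixture."""
    cfg = PipelineConfig(seed=1, phases=("planning",), n_perm=10_000)
    report, extras = run(cfg, keep_results=True)
    return {
        "config": cfg,
        "report": report,
        "results": extras["results"]["planning"],
        "stage": extras["stage"],
        "cohort": extras["cohort"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
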