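"""Shared synthetic fixtures.

All data is generated programmatically with fixed seeds; session scope
keeps the expensive cohorts shared across test modules.
"""

import numpy as np
import pytest

import pulsecount as pc


@pytest.fixture(scope="session")
def sv_cohort_small():
    """4k trials from a scalar-variability observer (k=0.3), fixed gamma."""
    cfg = pc.StimulusConfig.fixed_gamma()
    return pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.3}), 4000, seed=101)


@pytest.fixture(scope="session")
def sv_cohort_50k():
    """50k trials from a scalar-variability observer (k=0.3), default stimuli."""
    cfg = pc.StimulusConfig.unrestrained()
    return pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.3}), 50_000, seed=11)


@pytest.fixture(scope="session")
def jitter_cohort():
    """30k jittered-duration trials from a count-integrating observer.

    The 6-bin geometry concentrates trials at low counts, so equal-count
    trials (the ones that dissociate number from duration) are common.
    """
    cfg = pc.StimulusConfig.head_fixed(jitter=True)
    return pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.35}), 30_000, seed=103)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
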