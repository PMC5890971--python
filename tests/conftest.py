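"""Shared fixtures: phantoms and pipeline runs reused across the suite.

The paired inspiratory/expiratory runs at the default grid and the batch
of reduced-grid runs are expensive, so they are computed once per session
and shared by the unit and acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lobeseg.phantom import PhantomSpec, degrade_expiratory_contrast, generate_phantom
from lobeseg.pipeline import segment_lobes

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")

PAIRED_SEEDS = (1, 2, 3, 4, 5)
SMALL_SHAPE = (72, 96, 96)
N_SMALL = 20


@pytest.fixture(scope="session")
def default_phantom():
    """Default-grid phantom (seed 1): (spec, insp, exp, truth)."""
    spec = PhantomSpec(seed=1)
    insp, exp, truth = generate_phantom(spec)
    return spec, insp, exp, truth


@pytest.fixture(scope="session")
def paired_runs():
    """Default-grid paired studies at expiratory degrade level 0.5.

    Maps seed -> (spec, insp, exp, truth, result_insp, result_exp).
    """
    out = {}
    for seed in PAIRED_SEEDS:
        spec = degrade_expiratory_contrast(PhantomSpec(seed=seed), 0.5)
        insp, exp, truth = generate_phantom(spec)
        out[seed] = (spec, insp, exp, truth, segment_lobes(insp), segment_lobes(exp))
    return out


@pytest.fixture(scope="session")
def small_runs():
    """Reduced-grid inspiratory pipeline runs for batch invariants.

    Maps seed -> (truth, result) for 20 seeds at a 72x96x96 grid.
    """
    out = {}
    for seed in range(N_SMALL):
        spec = dataclasses.replace(PhantomSpec(seed=seed), shape=SMALL_SHAPE)
        insp, _exp, truth = generate_phantom(spec)
        out[seed] = (truth, segment_lobes(insp))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
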