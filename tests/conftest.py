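"""Shared fixtures: the default phantom cohort and its analysis, computed once.

The cohort seed is fixed so that every stochastic check in the suite is a
deterministic regression test.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eitroi
from eitroi import PhantomParams, StudyConfig, generate_cohort, run_study
from dataclasses import replace

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Single fixed seed for every cohort-level check in the suite.
COHORT_SEED = 12345


@pytest.fixture(scope="session")
def valid_32() -> np.ndarray:
    return eitroi.default_pixel_mask(32, 32)


@pytest.fixture(scope="session")
def default_cohort():
    """24 ARDS / 12 control subjects under the default study conditions."""
    return generate_cohort(24, 12, PhantomParams(), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_bundle(default_cohort):
    return run_study(default_cohort, StudyConfig())


@pytest.fixture(scope="session")
def null_bundle():
    """Same cohort sizes and seed, but the ARDS disease model disabled."""
    params = replace(PhantomParams(), defects_enabled=False)
    cohort = generate_cohort(24, 12, params, seed=COHORT_SEED)
    return run_study(cohort, StudyConfig())


def make_image(values, valid=None) -> eitroi.DeltaZImage:
    """Build a DeltaZImage from a plain array (full-grid valid by default)."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return eitroi.DeltaZImage(np.where(valid, values, np.nan), valid)
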