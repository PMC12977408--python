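"""Shared fixtures: fast synthetic dyads and derandomized hypothesis."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadsync import synth

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def short_params(**kw):
    """SimParams with reduced durations for fast unit tests."""
    defaults = dict(n_dyads=2, rng_seed=11, rest_duration=90.0,
                    task_duration=300.0, disruption_offset=150.0)
    defaults.update(kw)
    return synth.SimParams(**defaults)


@pytest.fixture(scope="session")
def short_dyad():
    """One fully generated short dyad (recording + ground truth)."""
    return synth.generate_dyad(short_params(), 0)


@pytest.fixture(scope="session")
def full_dyad():
    """One dyad at the study's real protocol durations (slow; shared)."""
    return synth.generate_dyad(synth.SimParams(n_dyads=1, rng_seed=5), 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
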