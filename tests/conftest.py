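"""Shared fixtures: expensive pipeline runs are computed once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from acrcycles import RunConfig, run_pipeline, wt_like_model

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model():
    return wt_like_model()


@pytest.fixture(scope="session")
def noiseless_result():
    return run_pipeline(RunConfig(seed=0, noise_frac=0.0))


@pytest.fixture(scope="session")
def noisy_result():
    return run_pipeline(RunConfig(seed=3, noise_frac=0.005))
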