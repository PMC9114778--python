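"""Shared fixtures: default synthetic sessions and offline results.

The heavyweight objects (two-repeat sessions at the study's default
generator settings, the offline experiment over both modes and loads, the
chance-baseline image set) are computed once per test session and shared.
All seeds are fixed so every fixture is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sonomyo as so
from sonomyo import cli_runner as cr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gen_config() -> so.GeneratorConfig:
    """Default generator settings, seed fixed."""
    return so.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def templates(gen_config):
    return so.make_templates(gen_config)


@pytest.fixture(scope="session")
def experiment_config() -> cr.ExperimentConfig:
    return cr.ExperimentConfig(generator=so.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def offline_result(experiment_config) -> cr.OfflineResult:
    """The full default offline experiment: accuracy matrices and SSIM
    summaries for static/dynamic x load A/B."""
    return cr.run_offline_experiment(experiment_config)


@pytest.fixture(scope="session")
def static_session_b(gen_config):
    return so.generate_session(so.static_protocol(so.Load.LOAD_B), gen_config, seed=7)


@pytest.fixture(scope="session")
def dynamic_session_b(gen_config):
    return so.generate_session(so.dynamic_protocol(so.Load.LOAD_B), gen_config, seed=7)


@pytest.fixture(scope="session")
def chance_images():
    return so.generate_chance_images(n=100, sigma=0.101, seed=9)


@pytest.fixture(scope="session")
def chance_result(chance_images):
    return so.chance_baseline(chance_images)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
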