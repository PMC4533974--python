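"""Shared fixtures: RNGs, tiny configurations, and the reduced-scale study.

The reduced-scale ("desk") conditions — 101x101 grid, capacity 10, severity
5, 3000 generations, 20 seeded runs per condition — are the package's study
conditions for the ordinal claims; they are expensive (minutes), so they are
session-scoped and built lazily only by the tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import extinctsim as xs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config() -> xs.SimulationConfig:
    """A seconds-scale configuration for unit-level runs."""
    return xs.SimulationConfig(
        grid_width=21, grid_height=21, niche_capacity=5, generations=100, rng_seed=7
    )


def _desk(name: str, schedule: xs.ExtinctionSchedule | None) -> xs.ConditionResult:
    return xs.run_condition(xs.make_condition(name, "desk", schedule=schedule, base_seed=1))


@pytest.fixture(scope="session")
def desk_control() -> xs.ConditionResult:
    return _desk("control", None)


@pytest.fixture(scope="session")
def desk_ext200() -> xs.ConditionResult:
    return _desk("ext_200", xs.ExtinctionSchedule.fixed(200))


@pytest.fixture(scope="session")
def desk_ext400() -> xs.ConditionResult:
    return _desk("ext_400", xs.ExtinctionSchedule.fixed(400))


@pytest.fixture(scope="session")
def desk_ext800() -> xs.ConditionResult:
    return _desk("ext_800", xs.ExtinctionSchedule.fixed(800))


@pytest.fixture(scope="session")
def desk_random() -> xs.ConditionResult:
    return _desk("ext_random", xs.ExtinctionSchedule.random_uniform(200, 800))
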