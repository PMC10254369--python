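"""Shared fixtures.

Heavy artifacts (explorations, the replay experiment, the saddle oracle) are
session-scoped: they are study conditions shared by many tests, and each is
deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from forcepath import MullerBrown
from forcepath.fixtures import FixtureSpec, make_fixture
from forcepath.oracles import barrier_catalog, surface_stationary_points
from forcepath.surrogate import ReplayConfig, replay_experiment


@pytest.fixture(scope="session")
def mb_potential():
    return MullerBrown()


@pytest.fixture(scope="session")
def mb_oracle(mb_potential):
    """Dense-grid + Newton stationary-point catalog of the Müller–Brown surface."""
    st = surface_stationary_points(mb_potential, n_grid=40)
    return {"stationary": st, "catalog": barrier_catalog(mb_potential, st)}


@pytest.fixture(scope="session")
def mb_fixture():
    return make_fixture(FixtureSpec("muller_brown", rng_seed=0))


@pytest.fixture(scope="session")
def wall_fixture():
    return make_fixture(FixtureSpec("wall_channel", rng_seed=0))


@pytest.fixture(scope="session")
def trimer_fixture():
    return make_fixture(FixtureSpec("morse_trimer", rng_seed=0))


@pytest.fixture(scope="session")
def replay_report():
    """Full surrogate-replay experiment on the wall fixture (seed 0)."""
    return replay_experiment(ReplayConfig(rng_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
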