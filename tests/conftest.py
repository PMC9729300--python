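import numpy as np
import pytest

import footsim as fs
from footsim.engine import SimulationConfig, SimulationTrace


@pytest.fixture(scope="session")
def pitch():
    return fs.PitchConfig()


@pytest.fixture(scope="session")
def formation_a(pitch):
    return fs.build_formation("3-5-2", "A", pitch)


@pytest.fixture(scope="session")
def formation_b(pitch):
    return fs.build_formation("3-5-2", "B", pitch)


@pytest.fixture(scope="session")
def roster():
    return fs.default_roster()


@pytest.fixture()
def match_state(roster, formation_a, formation_b, pitch):
    return fs.init_match(roster, formation_a, formation_b, pitch,
                         rng=np.random.default_rng(99))


@pytest.fixture(scope="session")
def c1_trace():
    """A short default-configuration run shared across tests."""
    return fs.run(fs.preset("C1", ticks=600, seed=7))


@pytest.fixture(scope="session")
def c2_trace():
    """A short no-energy-consumption run."""
    return fs.run(fs.preset("C2", ticks=400, seed=7))


def make_toy_trace(
    pos,
    heading=None,
    action=None,
    ball_pos=None,
    energy=None,
    possessor=None,
    events=(),
    roles=None,
    team=None,
    config=None,
):
    """Hand-assembled trace for analytics unit tests.

    ``pos`` has shape (T, n_players, 2); missing pieces get neutral
    defaults.  n_players may be below 22 for toy cases.
    """
    pos = np.asarray(pos, dtype=float)
    n_ticks, n_players = pos.shape[0], pos.shape[1]
    return SimulationTrace(
        config=config if config is not None else SimulationConfig(ticks=max(n_ticks, 1)),
        roles=list(roles) if roles is not None else ["rF"] * n_players,
        team=(
            np.asarray(team, dtype=np.int8)
            if team is not None
            else np.zeros(n_players, dtype=np.int8)
        ),
        pos=pos,
        heading=(
            np.asarray(heading, dtype=float)
            if heading is not None
            else np.zeros((n_ticks, n_players))
        ),
        energy=(
            np.asarray(energy, dtype=float)
            if energy is not None
            else np.full((n_ticks, n_players), 100.0)
        ),
        action=(
            np.asarray(action, dtype=np.int8)
            if action is not None
            else np.ones((n_ticks, n_players), dtype=np.int8)
        ),
        ball_pos=(
            np.asarray(ball_pos, dtype=float)
            if ball_pos is not None
            else np.zeros((n_ticks, 2))
        ),
        possessor=(
            np.asarray(possessor, dtype=np.int8)
            if possessor is not None
            else np.full(n_ticks, -1, dtype=np.int8)
        ),
        events=list(events),
    )
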