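"""Player and ball state, attribute roster, energy dynamics and kinematics.

Players are point vector-agents.  Each carries the endogenous attribute
set (energy, stamina, pace, shooting, agility, teamwork), all on a 0-100
scale.  Energy drains over time as a function of stamina and the distance
covered; the other attributes are static bases whose *effective* values
shrink with the energy level.

The per-tick kinematic constraints are a maximum step length of 1 m and a
maximum turning angle of 180 degrees per 100 ms tick; the actual step is
the cap scaled by the player's effective pace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import (
    Formation,
    GOALKEEPER_ROLE,
    PitchConfig,
    RoleBox,
    clamp_to_pitch,
)

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "PlayerAttributes",
    "PlayerState",
    "BallState",
    "MatchState",
    "RosterError",
    "EnergyParams",
    "KinematicParams",
    "load_roster",
    "default_roster",
    "init_match",
    "decay_energy",
    "energy_decrement",
    "effective_attribute",
    "kinematic_step",
    "move_with_constraints",
    "wrap_angle",
]

ATTRIBUTE_COLUMNS = (
    "id",
    "team",
    "role",
    "energy",
    "stamina",
    "pace",
    "shooting",
    "agility",
    "teamwork",
)

_STATIC_BASES = ("stamina", "pace", "shooting", "agility", "teamwork")

FREE_BALL = -1


class RosterError(ValueError):
    """Raised when the attribute roster violates its schema."""


@dataclass(frozen=True)
class PlayerAttributes:
    """Endogenous abilities of one player (0-100 scales)."""

    id: int
    team: str
    role_label: str
    energy: float
    stamina: float
    pace: float
    shooting: float
    agility: float
    teamwork: float

    def __post_init__(self) -> None:
        for name in ("energy",) + _STATIC_BASES:
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise RosterError(f"{name}={value} for player {self.id} not in [0, 100]")


@dataclass
class PlayerState:
    """Dynamic state of one player at a tick."""

    position: np.ndarray
    heading: float  # degrees in (-180, 180], 0 points toward +x
    energy: float
    current_action: int | None = None
    marked_opponent: int | None = None


@dataclass
class BallState:
    """The ball is a passive actor: carried, in flight, or at rest."""

    position: np.ndarray
    velocity: np.ndarray
    possessor: int = FREE_BALL  # player index 0-21, or FREE_BALL
    last_team: int = FREE_BALL  # team (0/1) that last possessed the ball
    # flight bookkeeping for pass/shot resolution
    launcher: int = FREE_BALL
    launch_kind: str | None = None  # "pass" | "shot"
    launch_position: np.ndarray | None = None
    launch_dist_to_goal: np.ndarray | None = None  # per player, at launch
    # last flight segment (pre-clamp endpoint) for goal-line crossing tests
    prev_position: np.ndarray | None = None
    raw_position: np.ndarray | None = None

    @property
    def in_flight(self) -> bool:
        return self.possessor == FREE_BALL and float(np.hypot(*self.velocity)) > 0.0


@dataclass
class EnergyParams:
    """Linear energy-decay model.

    Per tick a player loses
    ``base_rate * (1 + (100 - stamina)/100) * (0.5 + step_length)``
    energy points, floored at zero: low stamina and long steps drain
    faster, and even a stationary player pays half the base cost.
    ``base_rate`` defaults to 0.005 so that energy declines visibly
    (tens of points) over a 5000-tick horizon.
    """

    base_rate: float = 0.005
    #: fraction of the base attribute retained at zero energy
    floor_fraction: float = 0.5
    enabled: bool = True


@dataclass
class KinematicParams:
    """Per-tick movement limits."""

    max_step: float = 1.0  # metres per tick at effective pace 100
    max_turn: float = 180.0  # degrees per tick


def load_roster(source) -> pd.DataFrame:
    """Read an attribute roster from a CSV path, file object or DataFrame.

    The table must have exactly 22 rows with columns
    ``id, team, role, energy, stamina, pace, shooting, agility, teamwork``
    where ids 1-11 are team A and 12-22 team B.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
    if missing:
        raise RosterError(f"roster missing columns: {', '.join(missing)}")
    if len(df) != 22:
        raise RosterError(f"roster must have exactly 22 rows, got {len(df)}")
    df = df.sort_values("id").reset_index(drop=True)
    if list(df["id"]) != list(range(1, 23)):
        raise RosterError("roster ids must be exactly 1..22")
    expected_team = ["A"] * 11 + ["B"] * 11
    if list(df["team"]) != expected_team:
        raise RosterError("ids 1-11 must be team A and 12-22 team B")
    for name in ("energy",) + _STATIC_BASES:
        values = df[name].to_numpy(dtype=float)
        if np.any((values < 0) | (values > 100)):
            raise RosterError(f"attribute {name} outside [0, 100]")
    return df


def default_roster() -> pd.DataFrame:
    """The packaged 22-player attribute roster."""
    text = resources.files("footsim").joinpath("data/roster.csv").read_text()
    return load_roster(StringIO(text))


def effective_attribute(base: float, energy: float, params: EnergyParams | None = None) -> float:
    """Scale a static base attribute by the current energy level.

    Linear interpolation between ``floor_fraction * base`` at zero energy
    and ``base`` at full energy; never negative, never exceeds the base.
    """
    params = params if params is not None else EnergyParams()
    frac = params.floor_fraction + (1.0 - params.floor_fraction) * (energy / 100.0)
    return base * frac


def energy_decrement(stamina, step_length, params: EnergyParams):
    """Per-tick energy loss; works on scalars or aligned arrays."""
    return params.base_rate * (1.0 + (100.0 - stamina) / 100.0) * (0.5 + step_length)


def decay_energy(
    state: PlayerState,
    attrs: PlayerAttributes,
    step_length: float,
    params: EnergyParams | None = None,
) -> float:
    """New energy after one tick of motion (floored at 0).

    With consumption disabled (configuration C2) the energy is returned
    unchanged.
    """
    params = params if params is not None else EnergyParams()
    if not params.enabled:
        return state.energy
    return max(0.0, state.energy - float(energy_decrement(attrs.stamina, step_length, params)))


def wrap_angle(angle: float) -> float:
    """Normalize an angle in degrees to (-180, 180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def kinematic_step(
    position: np.ndarray,
    heading: float,
    target: Sequence[float],
    effective_pace: float,
    pitch: PitchConfig,
    kin: KinematicParams,
) -> tuple[np.ndarray, float]:
    """Low-level constrained step shared by the engine and the public API.

    Returns the new (position, heading).  The step length is capped at
    ``max_step * effective_pace / 100``, the position is clamped to the
    pitch, the turn is capped at ``max_turn`` and the heading follows the
    realised displacement (unchanged when there is none).
    """
    dx = target[0] - position[0]
    dy = target[1] - position[1]
    dist = math.hypot(dx, dy)
    if dist < 1e-12:
        return position, heading
    step = min(dist, kin.max_step * effective_pace / 100.0)
    new = clamp_to_pitch(
        (position[0] + dx / dist * step, position[1] + dy / dist * step), pitch
    )
    moved_x = new[0] - position[0]
    moved_y = new[1] - position[1]
    if math.hypot(moved_x, moved_y) < 1e-12:
        return position, heading
    desired = math.degrees(math.atan2(moved_y, moved_x))
    turn = wrap_angle(desired - heading)
    turn = max(-kin.max_turn, min(kin.max_turn, turn))
    return new, wrap_angle(heading + turn)


def move_with_constraints(
    state: PlayerState,
    target: Sequence[float],
    attrs: PlayerAttributes,
    pitch: PitchConfig,
    kin: KinematicParams | None = None,
    energy_params: EnergyParams | None = None,
) -> PlayerState:
    """One constrained kinematic step toward ``target``.

    The displacement is capped at ``max_step * effective_pace / 100``,
    the result is clamped to the pitch, and the heading turns to point
    along the realised displacement (unchanged when there is none).
    """
    kin = kin if kin is not None else KinematicParams()
    pace = effective_attribute(attrs.pace, state.energy, energy_params)
    new, heading = kinematic_step(
        np.asarray(state.position, dtype=float), state.heading, target, pace, pitch, kin
    )
    if heading == state.heading and np.array_equal(new, np.asarray(state.position)):
        return state
    return replace(state, position=new, heading=heading)


@dataclass
class MatchState:
    """Array-backed state of one match: 22 players, one ball.

    Player quantities are stored as aligned arrays indexed 0-21 (public
    player ids are index + 1).  Team 0 is A (attacks +x), team 1 is B.
    """

    pitch: PitchConfig
    formation_a: Formation
    formation_b: Formation
    roles: list[str]
    team: np.ndarray  # int8, 0=A 1=B
    stamina: np.ndarray
    pace: np.ndarray
    shooting: np.ndarray
    agility: np.ndarray
    teamwork: np.ndarray
    energy: np.ndarray
    pos: np.ndarray  # (22, 2)
    heading: np.ndarray  # degrees
    boxes: list[RoleBox]
    box_centres: np.ndarray  # (22, 2)
    is_gk: np.ndarray
    is_defender: np.ndarray
    ball: BallState = field(default_factory=lambda: BallState(np.zeros(2), np.zeros(2)))
    marking: np.ndarray | None = None  # fixed man-to-man assignment, index per player
    #: marking plan per team, ("man-to-man" | "zonal")
    marking_plan: tuple[str, str] = ("man-to-man", "man-to-man")
    rng: np.random.Generator | None = None

    def attacking_sign(self, idx: int) -> int:
        """+1 if the player attacks the +x goal, else -1."""
        return 1 if self.team[idx] == 0 else -1

    def team_indices(self, team: int) -> np.ndarray:
        return np.nonzero(self.team == team)[0]

    def opponents_of(self, idx: int) -> np.ndarray:
        return np.nonzero(self.team != self.team[idx])[0]

    def attributes(self, idx: int) -> PlayerAttributes:
        return PlayerAttributes(
            id=idx + 1,
            team="A" if self.team[idx] == 0 else "B",
            role_label=self.roles[idx],
            energy=float(self.energy[idx]),
            stamina=float(self.stamina[idx]),
            pace=float(self.pace[idx]),
            shooting=float(self.shooting[idx]),
            agility=float(self.agility[idx]),
            teamwork=float(self.teamwork[idx]),
        )

    def player_state(self, idx: int) -> PlayerState:
        return PlayerState(
            position=self.pos[idx].copy(),
            heading=float(self.heading[idx]),
            energy=float(self.energy[idx]),
        )

    def effective(self, attribute: str, idx: int, params: EnergyParams | None = None) -> float:
        base = float(getattr(self, attribute)[idx])
        return effective_attribute(base, float(self.energy[idx]), params)


def _kickoff_index(state: MatchState, team: int) -> int:
    """The team's most advanced role-box centre (ties to the lower id)."""
    members = state.team_indices(team)
    sign = 1 if team == 0 else -1
    advancement = sign * state.box_centres[members, 0]
    return int(members[int(np.argmax(advancement))])


def place_kickoff(state: MatchState, team: int) -> int:
    """Reset all players to their box centres and give ``team`` the kickoff.

    The kickoff taker is moved to the pitch centre with the ball.  Returns
    the kickoff taker's index.
    """
    state.pos[:] = state.box_centres
    for idx in range(22):
        state.heading[idx] = 0.0 if state.team[idx] == 0 else 180.0
    taker = _kickoff_index(state, team)
    state.pos[taker] = (0.0, 0.0)
    state.ball.position = np.zeros(2)
    state.ball.velocity = np.zeros(2)
    state.ball.possessor = taker
    state.ball.last_team = team
    state.ball.launcher = FREE_BALL
    state.ball.launch_kind = None
    state.ball.launch_position = None
    state.ball.launch_dist_to_goal = None
    return taker


def init_match(
    roster: pd.DataFrame,
    formation_a: Formation,
    formation_b: Formation,
    pitch: PitchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MatchState:
    """Breed the 22 players and place them for kickoff.

    Players take the role-boxes of their team's formation in roster order
    (so the roster's ``role`` column is nominal; the formation decides the
    actual role labels).  Everyone starts at their role-box centre facing
    the opponent goal, except the kickoff taker -- team A's most advanced
    player -- who starts at the pitch centre with the ball.
    """
    pitch = pitch if pitch is not None else PitchConfig()
    roster = load_roster(roster)
    boxes: list[RoleBox] = []
    roles: list[str] = []
    for i in range(22):
        formation = formation_a if i < 11 else formation_b
        box = replace(formation.role_boxes[i % 11], owner=i + 1)
        boxes.append(box)
        roles.append(box.role_label)
    team = np.array([0] * 11 + [1] * 11, dtype=np.int8)
    box_centres = np.array([b.centre for b in boxes])
    is_gk = np.array([r == GOALKEEPER_ROLE for r in roles])
    is_defender = np.array([r.endswith("B") for r in roles])
    marking = np.array([(i + 11) % 22 for i in range(22)], dtype=np.int64)
    state = MatchState(
        pitch=pitch,
        formation_a=formation_a,
        formation_b=formation_b,
        roles=roles,
        team=team,
        stamina=roster["stamina"].to_numpy(dtype=float),
        pace=roster["pace"].to_numpy(dtype=float),
        shooting=roster["shooting"].to_numpy(dtype=float),
        agility=roster["agility"].to_numpy(dtype=float),
        teamwork=roster["teamwork"].to_numpy(dtype=float),
        energy=roster["energy"].to_numpy(dtype=float),
        pos=box_centres.copy(),
        heading=np.where(team == 0, 0.0, 180.0).astype(float),
        boxes=boxes,
        box_centres=box_centres,
        is_gk=is_gk,
        is_defender=is_defender,
        marking=marking,
        rng=rng,
    )
    place_kickoff(state, team=0)
    return state
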