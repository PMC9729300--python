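"""Turn selected actions into movement targets and ball commands, and run
the ball mechanics: flight, interception, possession contests, goal
detection and kickoff resets.

The ball is a passive actor.  Possessed, it sits at its possessor's feet
and moves with them; launched (pass or shot), it flies in a straight line
at a fixed initial speed, slowing by a per-tick friction factor, until a
player close enough to its path intercepts it, it comes to rest, leaves
through a goal mouth, or is stopped by the pitch boundary (there are no
throw-ins: the boundary simply stops the ball).

Possession contests go to the contender with the highest effective
agility; exact ties are broken uniformly at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .agents import (
    FREE_BALL,
    EnergyParams,
    MatchState,
    place_kickoff,
)
from .decision import Action, DecisionParams, point_segment_distance

__all__ = [
    "EventRecord",
    "BallParams",
    "ActionParams",
    "PASS_COMPLETE",
    "POSSESSION_CHANGE",
    "SHOT",
    "GOAL",
    "plan_action",
    "select_pass_target",
    "launch_pass",
    "launch_shot",
    "update_ball",
    "resolve_possession",
    "detect_goal_and_reset",
]

PASS_COMPLETE = "pass_complete"
POSSESSION_CHANGE = "possession_change_between_teams"
SHOT = "shot"
GOAL = "goal"

_TEAM_LETTER = ("A", "B")


@dataclass(frozen=True)
class EventRecord:
    """One discrete match event.

    ``from_player``/``to_player`` are public 1-based player ids.  Team
    possession changes are team-level only: they carry the winning team
    but no player pair.
    """

    tick: int
    kind: str
    from_player: int | None
    to_player: int | None
    team: str

    def __post_init__(self) -> None:
        if self.kind == PASS_COMPLETE:
            if self.from_player is None or self.to_player is None:
                raise ValueError("pass_complete needs both players")


@dataclass
class BallParams:
    """Ball kinematics and contest geometry (metres, metres/tick)."""

    pass_speed: float = 3.0
    shot_speed: float = 5.0
    friction: float = 0.9  # per-tick speed retention of a free ball
    interception_radius: float = 1.0
    possession_radius: float = 1.0
    stop_speed: float = 0.25  # below this a flying ball is at rest
    #: std-dev of shot aim noise at zero effective shooting, metres
    aim_noise_scale: float = 3.0

    def flight_range(self, launch_speed: float) -> float:
        """Distance a launch covers before friction stops it."""
        distance = 0.0
        speed = launch_speed
        while speed >= self.stop_speed:
            distance += speed
            speed *= self.friction
        return distance


@dataclass
class ActionParams:
    """Geometry of action planning."""

    #: grid spacing for the Act7 open-space search, metres
    act7_grid_step: float = 2.0
    #: how far from the own goal centre the goalkeeper interposes
    gk_guard_distance: float = 6.0


@lru_cache(maxsize=128)
def _box_grid(xmin: float, ymin: float, xmax: float, ymax: float, step: float) -> np.ndarray:
    """Candidate points covering a role-box, corners included."""
    xs = np.arange(xmin, xmax + 1e-9, step)
    ys = np.arange(ymin, ymax + 1e-9, step)
    if xs[-1] < xmax:
        xs = np.append(xs, xmax)
    if ys[-1] < ymax:
        ys = np.append(ys, ymax)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _mark_target(state: MatchState, idx: int, positions: np.ndarray) -> int:
    """Opponent to mark under the player's team marking plan."""
    plan = state.marking_plan[int(state.team[idx])]
    if plan == "man-to-man":
        return int(state.marking[idx])
    # zonal: the opponent currently nearest the player's role-box centre
    opponents = state.opponents_of(idx)
    deltas = positions[opponents] - state.box_centres[idx]
    dists = np.hypot(deltas[:, 0], deltas[:, 1])
    order = np.lexsort((opponents, dists))
    return int(opponents[order[0]])


def plan_action(
    state: MatchState,
    idx: int,
    action: Action,
    decision_params: DecisionParams | None = None,
    action_params: ActionParams | None = None,
    rng: np.random.Generator | None = None,
    positions: np.ndarray | None = None,
) -> tuple[np.ndarray, str | None]:
    """Movement target and ball command for one selected action.

    Returns ``(target, command)`` with command ``None`` (just move),
    ``"carry"`` (move with the ball), ``"pass"`` or ``"shoot"``.
    ``positions`` may supply a perception snapshot of player positions;
    the live positions are used otherwise.
    """
    dp = decision_params if decision_params is not None else DecisionParams()
    ap = action_params if action_params is not None else ActionParams()
    rng = rng if rng is not None else (state.rng or np.random.default_rng())
    pos = positions if positions is not None else state.pos
    me = state.pos[idx]
    box = state.boxes[idx]

    if action is Action.ACT1:
        target = np.array(
            [rng.uniform(box.xmin, box.xmax), rng.uniform(box.ymin, box.ymax)]
        )
        return target, None

    if action is Action.ACT2:
        ball = state.ball.position
        if state.is_gk[idx]:
            # interpose on the ball--own-goal segment
            goal = state.pitch.goal_centre(-state.attacking_sign(idx))
            to_ball = ball - goal
            dist = float(np.hypot(*to_ball))
            if dist < 1e-9:
                return goal.copy(), None
            depth = min(ap.gk_guard_distance, dist)
            return goal + to_ball / dist * depth, None
        return pos[_mark_target(state, idx, pos)].copy(), None

    if action is Action.ACT3:
        return state.ball.position.copy(), None

    if action is Action.ACT4:
        return state.pitch.goal_centre(state.attacking_sign(idx)).copy(), "carry"

    if action is Action.ACT5:
        return me.copy(), "pass"

    if action is Action.ACT6:
        return me.copy(), "shoot"

    # Act7: the role-box point farthest from the nearest opponent
    grid = _box_grid(box.xmin, box.ymin, box.xmax, box.ymax, ap.act7_grid_step)
    opponents = state.opponents_of(idx)
    diff = grid[:, None, :] - pos[opponents][None, :, :]
    openness = np.min(np.hypot(diff[:, :, 0], diff[:, :, 1]), axis=1)
    return grid[int(np.argmax(openness))].copy(), None


def _dist_to_goal_line(state: MatchState, team: int, positions: np.ndarray) -> np.ndarray:
    """Distance of every player to the goal line ``team`` attacks."""
    sign = 1.0 if team == 0 else -1.0
    return state.pitch.half_length - sign * positions[:, 0]


def select_pass_target(
    state: MatchState, passer: int, params: BallParams | None = None
) -> int | None:
    """Receiver for a forward pass, or None when no teammate is ahead.

    Only teammates strictly closer to the opponent goal line and within
    the ball's travel range qualify (no backward passes, no hopeful balls
    the ball physics cannot deliver).  Among them the most open one
    (largest distance to its nearest opponent) wins; ties break toward
    the shorter pass, then the lower id.
    """
    params = params if params is not None else BallParams()
    reach = params.flight_range(params.pass_speed)
    team = int(state.team[passer])
    adv = _dist_to_goal_line(state, team, state.pos)
    teammates = [
        j
        for j in state.team_indices(team)
        if j != passer
        and adv[j] < adv[passer]
        and float(np.hypot(*(state.pos[j] - state.pos[passer]))) <= reach
    ]
    if not teammates:
        return None
    opponents = state.opponents_of(passer)
    best = None
    best_key = None
    for j in teammates:
        deltas = state.pos[opponents] - state.pos[j]
        openness = float(np.min(np.hypot(deltas[:, 0], deltas[:, 1])))
        pass_len = float(np.hypot(*(state.pos[j] - state.pos[passer])))
        key = (-openness, pass_len, j)
        if best_key is None or key < best_key:
            best_key = key
            best = j
    return best


def launch_pass(state: MatchState, passer: int, receiver: int, params: BallParams) -> None:
    """Put the ball in flight from ``passer`` toward ``receiver``."""
    ball = state.ball
    direction = state.pos[receiver] - ball.position
    dist = float(np.hypot(*direction))
    if dist < 1e-9:
        direction = np.array([float(state.attacking_sign(passer)), 0.0])
        dist = 1.0
    ball.velocity = direction / dist * params.pass_speed
    ball.possessor = FREE_BALL
    ball.launcher = passer
    ball.launch_kind = "pass"
    ball.launch_position = ball.position.copy()
    ball.launch_dist_to_goal = _dist_to_goal_line(state, int(state.team[passer]), state.pos)


def launch_shot(
    state: MatchState,
    shooter: int,
    params: BallParams,
    rng: np.random.Generator,
    energy_params: EnergyParams | None = None,
) -> None:
    """Launch the ball toward a random point of the opponent goal mouth.

    The aim point is uniform on the goal mouth plus Gaussian noise that
    shrinks with the shooter's effective shooting ability.  A defensive
    clearance uses the same mechanics: the opponent goal is upfield.
    """
    ball = state.ball
    pitch = state.pitch
    sign = state.attacking_sign(shooter)
    half_mouth = pitch.goal_width / 2.0
    shooting = state.effective("shooting", shooter, energy_params)
    noise_sd = params.aim_noise_scale * (100.0 - shooting) / 100.0
    aim_y = rng.uniform(-half_mouth, half_mouth) + rng.normal(0.0, noise_sd)
    aim = np.array([math.copysign(pitch.half_length, sign), aim_y])
    direction = aim - ball.position
    dist = float(np.hypot(*direction))
    if dist < 1e-9:
        direction, dist = np.array([float(sign), 0.0]), 1.0
    ball.velocity = direction / dist * params.shot_speed
    ball.possessor = FREE_BALL
    ball.launcher = shooter
    ball.launch_kind = "shot"
    ball.launch_position = ball.position.copy()
    ball.launch_dist_to_goal = None


def resolve_possession(
    contenders: Sequence[int],
    state: MatchState,
    params: BallParams | None = None,
    rng: np.random.Generator | None = None,
    energy_params: EnergyParams | None = None,
) -> int:
    """Winner of a possession contest: highest effective agility.

    Exact ties are broken uniformly at random with the run RNG.
    """
    if len(contenders) == 0:
        raise ValueError("possession contest needs at least one contender")
    rng = rng if rng is not None else (state.rng or np.random.default_rng())
    agilities = np.array(
        [state.effective("agility", j, energy_params) for j in contenders]
    )
    best = np.max(agilities)
    tied = [c for c, a in zip(contenders, agilities) if a >= best - 1e-12]
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[int(rng.integers(len(tied)))])


def _take_possession(
    state: MatchState,
    winner: int,
    events: list[EventRecord],
    tick: int,
) -> None:
    """Give the ball to ``winner`` and emit the bookkeeping events."""
    ball = state.ball
    winner_team = int(state.team[winner])
    if (
        ball.launch_kind == "pass"
        and ball.launcher != FREE_BALL
        and winner != ball.launcher
        and int(state.team[ball.launcher]) == winner_team
        and ball.launch_dist_to_goal is not None
        and ball.launch_dist_to_goal[winner] < ball.launch_dist_to_goal[ball.launcher]
    ):
        events.append(
            EventRecord(
                tick=tick,
                kind=PASS_COMPLETE,
                from_player=ball.launcher + 1,
                to_player=winner + 1,
                team=_TEAM_LETTER[winner_team],
            )
        )
    if ball.last_team != FREE_BALL and winner_team != ball.last_team:
        events.append(
            EventRecord(
                tick=tick,
                kind=POSSESSION_CHANGE,
                from_player=None,
                to_player=None,
                team=_TEAM_LETTER[winner_team],
            )
        )
    ball.possessor = winner
    ball.last_team = winner_team
    ball.position = state.pos[winner].copy()
    ball.velocity = np.zeros(2)
    ball.launcher = FREE_BALL
    ball.launch_kind = None
    ball.launch_position = None
    ball.launch_dist_to_goal = None
    ball.raw_position = None  # an intercepted flight cannot score


def update_ball(
    state: MatchState,
    params: BallParams,
    pressing: np.ndarray | None = None,
    events: list[EventRecord] | None = None,
    tick: int = 0,
    rng: np.random.Generator | None = None,
    energy_params: EnergyParams | None = None,
) -> None:
    """Advance the ball one tick (in place).

    * possessed: the ball moves with its possessor; opposing pressers
      (``pressing`` marks the players that chose Act3 this tick) within
      the possession radius force a contest with the carrier;
    * in flight: the ball advances along its velocity, players within the
      interception radius of the flight segment contest it, friction
      slows it, the pitch boundary stops it;
    * at rest and free: any player within the possession radius collects
      it (contested when several are).
    The pass/shot launcher cannot intercept their own launch while it is
    still in flight.
    """
    events = events if events is not None else []
    rng = rng if rng is not None else (state.rng or np.random.default_rng())
    ball = state.ball
    ball.prev_position = ball.position.copy()
    ball.raw_position = None

    if ball.possessor != FREE_BALL:
        carrier = ball.possessor
        ball.position = state.pos[carrier].copy()
        if pressing is not None:
            opponents = [
                int(j)
                for j in state.opponents_of(carrier)
                if pressing[j]
                and float(np.hypot(*(state.pos[j] - ball.position)))
                <= params.possession_radius
            ]
            if opponents:
                winner = resolve_possession(
                    opponents + [carrier], state, params, rng, energy_params
                )
                if winner != carrier:
                    _take_possession(state, winner, events, tick)
        return

    speed = float(np.hypot(*ball.velocity))
    if speed > 0.0:
        raw = ball.position + ball.velocity
        ball.raw_position = raw.copy()
        launch_origin = ball.launch_position
        contenders = []
        for j in range(len(state.pos)):
            if j == ball.launcher:
                continue
            # a presser already inside the duel radius at the launch spot
            # was played past and cannot block the launch
            if (
                launch_origin is not None
                and float(np.hypot(*(state.pos[j] - launch_origin)))
                <= params.possession_radius
            ):
                continue
            if (
                point_segment_distance(state.pos[j], ball.position, raw)
                <= params.interception_radius
            ):
                contenders.append(j)
        if contenders:
            winner = resolve_possession(contenders, state, params, rng, energy_params)
            _take_possession(state, winner, events, tick)
            return
        clamped = np.array(
            [
                min(max(raw[0], -state.pitch.half_length), state.pitch.half_length),
                min(max(raw[1], -state.pitch.half_width), state.pitch.half_width),
            ]
        )
        ball.position = clamped
        if not np.array_equal(clamped, raw):
            ball.velocity = np.zeros(2)  # boundary stops the ball
        else:
            ball.velocity = ball.velocity * params.friction
            if float(np.hypot(*ball.velocity)) < params.stop_speed:
                ball.velocity = np.zeros(2)
        return

    # free ball at rest: adjacent players collect it
    contenders = [
        j
        for j in range(len(state.pos))
        if float(np.hypot(*(state.pos[j] - ball.position))) <= params.possession_radius
    ]
    if contenders:
        winner = resolve_possession(contenders, state, params, rng, energy_params)
        _take_possession(state, winner, events, tick)


def detect_goal_and_reset(
    state: MatchState,
    events: list[EventRecord] | None = None,
    tick: int = 0,
) -> EventRecord | None:
    """Emit a goal when the ball's last flight segment crossed a goal mouth.

    On a goal every player returns to their role-box centre and the
    conceding team kicks off.  Crossings outside the goal mouth are not
    goals (the boundary clamp has already stopped the ball).
    """
    ball = state.ball
    if ball.prev_position is None or ball.raw_position is None:
        return None
    events = events if events is not None else []
    x0, y0 = float(ball.prev_position[0]), float(ball.prev_position[1])
    x1, y1 = float(ball.raw_position[0]), float(ball.raw_position[1])
    half_len = state.pitch.half_length
    half_mouth = state.pitch.goal_width / 2.0
    for goal_sign, scoring_team in ((1.0, 0), (-1.0, 1)):
        line = goal_sign * half_len
        if (x0 - line) * (x1 - line) < 0 or (x1 == line and x0 != line):
            t = (line - x0) / (x1 - x0)
            y_cross = y0 + t * (y1 - y0)
            if abs(y_cross) <= half_mouth:
                scorer = ball.launcher if ball.launcher != FREE_BALL else None
                event = EventRecord(
                    tick=tick,
                    kind=GOAL,
                    from_player=None if scorer is None else scorer + 1,
                    to_player=None,
                    team=_TEAM_LETTER[scoring_team],
                )
                events.append(event)
                place_kickoff(state, team=1 - scoring_team)
                ball.prev_position = None
                ball.raw_position = None
                return event
    return None
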