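"""The purely reactive movement policy: classify the scenario, weigh the
causal factors, pick one of seven actions.

Every player, every tick, answers *who possesses the ball?* and lands in
exactly one of four perception scenarios; a small set of causal factors
(own abilities, ball and goal distances, opponents in the way, role-box
membership) then selects exactly one action:

* Act1  move randomly (within the role-box)
* Act2  mark the nearest opponent
* Act3  get possession of the ball
* Act4  carry the ball
* Act5  pass the ball
* Act6  shoot the ball
* Act7  open up space

The policy is memoryless: identical contexts always give identical
actions.  Only the two players closest to the ball (the 1st and 2nd
defenders) may press it, so at most two players per team choose Act3 at
any tick.

Distance thresholds ("close"/"far") and the skill mapping (dribbling :=
effective agility, passing := effective teamwork) are configurable in
:class:`DecisionParams`; the defaults are the package's own calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np

from .agents import FREE_BALL, MatchState, EnergyParams

__all__ = [
    "Scenario",
    "Action",
    "DecisionParams",
    "DecisionContext",
    "ContextError",
    "classify_scenario",
    "rank_defenders",
    "opponents_between",
    "point_segment_distance",
    "decide_action",
    "build_context",
]


class Scenario(Enum):
    OPPONENT_HAS_BALL = "opponent_has_ball"
    NO_ONE_HAS_BALL = "no_one_has_ball"
    I_HAVE_BALL = "i_have_ball"
    TEAMMATE_HAS_BALL = "teammate_has_ball"


class Action(IntEnum):
    ACT1 = 1  # move randomly
    ACT2 = 2  # mark the nearest opponent
    ACT3 = 3  # get possession of the ball
    ACT4 = 4  # carry the ball
    ACT5 = 5  # pass the ball
    ACT6 = 6  # shoot the ball
    ACT7 = 7  # open up space


class ContextError(ValueError):
    """Raised when a decision context contradicts the world state."""


@dataclass
class DecisionParams:
    """Thresholds and skill mapping of the decision policy (metres)."""

    ball_close: float = 15.0
    goal_close: float = 20.0
    opponent_close: float = 5.0
    corridor_width: float = 4.0
    #: an eligible presser may chase an opponent-held ball within this range
    pressing_range: float = 20.0
    #: attribute used as dribbling skill
    dribble_attribute: str = "agility"
    #: attribute used as passing skill
    pass_attribute: str = "teamwork"


@dataclass
class DecisionContext:
    """Everything the policy may look at for one player at one tick."""

    scenario: Scenario
    player_id: int  # index 0-21
    possessor_id: int  # index or FREE_BALL
    is_goalkeeper: bool
    is_defender: bool
    dist_ball: float
    dist_own_goal: float
    dist_opp_goal: float
    is_first_defender: bool
    is_second_defender: bool
    n_opponents_between: int
    nearest_opponent_dist: float
    would_leave_box: bool
    dribble_skill: float
    pass_skill: float
    params: DecisionParams

    def __post_init__(self) -> None:
        for name in ("dist_ball", "dist_own_goal", "dist_opp_goal", "nearest_opponent_dist"):
            if getattr(self, name) < 0:
                raise ContextError(f"{name} must be nonnegative")


def classify_scenario(state: MatchState, idx: int) -> Scenario:
    """Which of the four perception scenarios the player is in."""
    possessor = state.ball.possessor
    if possessor == FREE_BALL:
        return Scenario.NO_ONE_HAS_BALL
    if possessor == idx:
        return Scenario.I_HAVE_BALL
    if state.team[possessor] == state.team[idx]:
        return Scenario.TEAMMATE_HAS_BALL
    return Scenario.OPPONENT_HAS_BALL


def rank_defenders(
    state: MatchState, team: int, ball_position: np.ndarray | None = None
) -> tuple[int, int]:
    """The team's 1st and 2nd defenders.

    The 1st defender is the team member closest to the ball; the 2nd is
    the next closest (the immediate support).  Exact distance ties break
    toward the lower player id.
    """
    members = state.team_indices(team)
    if len(members) < 2:
        raise ValueError("a team needs at least 2 players to rank defenders")
    ball = ball_position if ball_position is not None else state.ball.position
    deltas = state.pos[members] - ball
    dists = np.hypot(deltas[:, 0], deltas[:, 1])
    order = np.lexsort((members, dists))  # distance, then id
    return int(members[order[0]]), int(members[order[1]])


def point_segment_distance(p, a, b) -> float:
    """Euclidean distance from point ``p`` to segment ``ab``."""
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    px, py = float(p[0]), float(p[1])
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * dx + (py - ay) * dy) / seg2
    t = max(0.0, min(1.0, t))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def opponents_between(
    state: MatchState,
    idx: int,
    frm: np.ndarray,
    to: np.ndarray,
    corridor_width: float | None = None,
    positions: np.ndarray | None = None,
) -> int:
    """Opposing outfielders inside the corridor from ``frm`` to ``to``.

    Counts opponents whose distance to the segment is at most half the
    corridor width.  The opposing goalkeeper is never counted.
    """
    if np.allclose(frm, to):
        raise ValueError("corridor endpoints must differ")
    params_width = corridor_width if corridor_width is not None else DecisionParams().corridor_width
    half = params_width / 2.0
    pos = positions if positions is not None else state.pos
    count = 0
    for j in state.opponents_of(idx):
        if state.is_gk[j]:
            continue
        if point_segment_distance(pos[j], frm, to) <= half:
            count += 1
    return count


def decide_action(ctx: DecisionContext) -> Action:
    """Map one decision context to exactly one action.

    The mapping is total: every consistent context yields an action.

    * OPPONENT_HAS_BALL -- press (Act3) when eligible (1st/2nd defender
      with the ball in pressing range), otherwise mark (Act2) if the ball
      is close, otherwise roam (Act1).
    * NO_ONE_HAS_BALL -- the 1st/2nd defenders chase the loose ball
      (Act3, no range cap so a dead ball is always collected); everyone
      else marks or roams by ball distance.
    * I_HAVE_BALL -- shooting chances are taken first: close to the
      opponent goal with fewer than two opponents in the corridor, or --
      for goalkeepers and defenders -- pressed close to the own goal
      (a clearance).  Otherwise carrying out of the role-box forces a
      pass; with a clear corridor (or one opponent but better dribbling
      than passing) the player carries, else passes.
    * TEAMMATE_HAS_BALL -- open up space inside the role-box (Act7).
    """
    s = ctx.scenario
    p = ctx.params
    if s is Scenario.I_HAVE_BALL and ctx.possessor_id != ctx.player_id:
        raise ContextError("scenario says I_HAVE_BALL but the possessor differs")
    if s is not Scenario.I_HAVE_BALL and ctx.possessor_id == ctx.player_id:
        raise ContextError("player possesses the ball but the scenario disagrees")

    if s is Scenario.OPPONENT_HAS_BALL:
        eligible = ctx.is_first_defender or ctx.is_second_defender
        if eligible and ctx.dist_ball <= p.pressing_range:
            return Action.ACT3
        if ctx.dist_ball <= p.ball_close:
            return Action.ACT2
        return Action.ACT1

    if s is Scenario.NO_ONE_HAS_BALL:
        if ctx.is_first_defender or ctx.is_second_defender:
            return Action.ACT3
        if ctx.dist_ball <= p.ball_close:
            return Action.ACT2
        return Action.ACT1

    if s is Scenario.I_HAVE_BALL:
        shooting_chance = (
            ctx.dist_opp_goal <= p.goal_close and ctx.n_opponents_between < 2
        )
        clearance = (
            (ctx.is_goalkeeper or ctx.is_defender)
            and ctx.dist_own_goal <= p.goal_close
            and ctx.nearest_opponent_dist <= p.opponent_close
        )
        if shooting_chance or clearance:
            return Action.ACT6
        if ctx.would_leave_box:
            return Action.ACT5
        if ctx.n_opponents_between == 0:
            return Action.ACT4
        if ctx.n_opponents_between == 1 and ctx.dribble_skill > ctx.pass_skill:
            return Action.ACT4
        return Action.ACT5

    return Action.ACT7


def build_context(
    state: MatchState,
    idx: int,
    params: DecisionParams,
    energy_params: EnergyParams | None = None,
    first_defender: int | None = None,
    second_defender: int | None = None,
    max_step: float = 1.0,
) -> DecisionContext:
    """Assemble the decision context for one player from the live state."""
    scenario = classify_scenario(state, idx)
    team = int(state.team[idx])
    if first_defender is None or second_defender is None:
        first_defender, second_defender = rank_defenders(state, team)
    sign = state.attacking_sign(idx)
    pos = state.pos[idx]
    own_goal = state.pitch.goal_centre(-sign)
    opp_goal = state.pitch.goal_centre(sign)
    dist_ball = float(np.hypot(*(state.ball.position - pos)))
    opponents = state.opponents_of(idx)
    opp_deltas = state.pos[opponents] - pos
    nearest_opp = float(np.min(np.hypot(opp_deltas[:, 0], opp_deltas[:, 1])))
    n_between = 0
    would_leave = False
    if scenario is Scenario.I_HAVE_BALL:
        n_between = opponents_between(state, idx, pos, opp_goal, params.corridor_width)
        to_goal = opp_goal - pos
        norm = float(np.hypot(*to_goal))
        if norm > 1e-9:
            ahead = pos + to_goal / norm * max_step
            would_leave = not state.boxes[idx].contains(ahead)
    return DecisionContext(
        scenario=scenario,
        player_id=idx,
        possessor_id=int(state.ball.possessor),
        is_goalkeeper=bool(state.is_gk[idx]),
        is_defender=bool(state.is_defender[idx]),
        dist_ball=dist_ball,
        dist_own_goal=float(np.hypot(*(own_goal - pos))),
        dist_opp_goal=float(np.hypot(*(opp_goal - pos))),
        is_first_defender=idx == first_defender,
        is_second_defender=idx == second_defender,
        n_opponents_between=n_between,
        nearest_opponent_dist=nearest_opp,
        would_leave_box=would_leave,
        dribble_skill=state.effective(params.dribble_attribute, idx, energy_params),
        pass_skill=state.effective(params.pass_attribute, idx, energy_params),
        params=params,
    )
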