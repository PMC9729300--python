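"""Verification and validation statistics for simulation traces.

Covers the toolkit used to accredit the simulator: per-tick action
frequency shares and their horizon representativeness, replicate
stabilization by coefficient of variation (CV), variability summaries at
player/role/team/aggregate level, dyadic relative orientation and
distance statistics, the pass/possession matrix, and role-box occupancy.

Player identifiers in this module are the public 1-based ids (1-11 team
A, 12-22 team B); the target of a dyadic statistic is ``"ball"`` or a
player id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .actions import GOAL, PASS_COMPLETE, POSSESSION_CHANGE, EventRecord
from .agents import FREE_BALL, init_match, default_roster
from .engine import SimulationTrace
from .environment import Formation, build_formation

__all__ = [
    "ACTION_LABELS",
    "OrientationHistogram",
    "PossessionMatrix",
    "HorizonSummary",
    "CVStabilization",
    "DistanceSummary",
    "action_frequency_series",
    "horizon_representativeness",
    "cv_stabilization",
    "variability_summary",
    "relative_orientation_histogram",
    "relative_distance_summary",
    "possession_matrix",
    "role_box_occupancy",
    "action_totals",
    "step_lengths",
    "heading_changes",
]

ACTION_LABELS = tuple(f"Act{i}" for i in range(1, 8))

#: the 36 signed 10-degree orientation classes, -170 .. 180
ORIENTATION_CLASSES = tuple(range(-170, 181, 10))


@dataclass(frozen=True)
class OrientationHistogram:
    """Shares (percent) of the 36 ten-degree relative-orientation classes.

    Class ``k`` covers signed relative orientations in
    ``[k-5, k+5)`` degrees (class 180 also absorbs the wrap-around);
    negative classes mean the player must turn left to face the target.
    """

    classes: tuple[int, ...]
    shares: np.ndarray  # percent, sums to 100
    player_id: int
    target: object

    def __post_init__(self) -> None:
        if len(self.classes) != 36 or len(self.shares) != 36:
            raise ValueError("orientation histogram needs exactly 36 classes")
        if abs(float(np.sum(self.shares)) - 100.0) > 1e-9:
            raise ValueError("orientation shares must sum to 100%")

    def share(self, class_label: int) -> float:
        return float(self.shares[self.classes.index(class_label)])


@dataclass(frozen=True)
class PossessionMatrix:
    """22 x 22 completed-pass counts plus per-team possession gains."""

    passes: np.ndarray  # (22, 22), row = from, column = to
    team_gains: dict

    @property
    def total_passes(self) -> int:
        return int(self.passes.sum())


@dataclass(frozen=True)
class HorizonSummary:
    """Mean action-share SD in two horizon windows."""

    per_action: pd.DataFrame  # index Act1..Act7, columns sd_first, sd_second
    mean_sd_first: float
    mean_sd_second: float
    relative_difference: float


@dataclass(frozen=True)
class CVStabilization:
    """Aggregated CV as a function of replicate count."""

    curve: pd.Series  # index k (replicate count), aggregated CV
    stabilization_count: int | None
    excluded_outcomes: tuple = ()


@dataclass(frozen=True)
class DistanceSummary:
    series: np.ndarray
    mean: float
    min: float
    max: float


class DataError(ValueError):
    """Inconsistent analytics input (e.g. a cross-team pass)."""


def _reset_tick_mask(trace: SimulationTrace) -> np.ndarray:
    """Boolean mask (length T-1) of tick transitions that cross a goal
    kickoff reset, where players are repositioned rather than moving."""
    mask = np.zeros(max(trace.n_ticks - 1, 0), dtype=bool)
    for e in trace.events:
        if e.kind == GOAL and 2 <= e.tick <= trace.n_ticks:
            mask[e.tick - 2] = True
    return mask


def step_lengths(trace: SimulationTrace, exclude_resets: bool = True) -> np.ndarray:
    """Per-transition step length of every player, shape (T-1, 22).

    With ``exclude_resets`` the transitions into a goal-kickoff tick are
    dropped: those reposition the players and are not kinematic steps.
    """
    diffs = np.diff(trace.pos, axis=0)
    steps = np.hypot(diffs[..., 0], diffs[..., 1])
    if exclude_resets:
        steps = steps[~_reset_tick_mask(trace)]
    return steps


def heading_changes(trace: SimulationTrace, exclude_resets: bool = True) -> np.ndarray:
    """Per-transition absolute heading change (degrees), shape (T-1, 22)."""
    diffs = np.diff(trace.heading, axis=0)
    wrapped = np.abs((diffs + 180.0) % 360.0 - 180.0)
    if exclude_resets:
        wrapped = wrapped[~_reset_tick_mask(trace)]
    return wrapped


def action_frequency_series(trace: SimulationTrace) -> pd.DataFrame:
    """Percent share of each action over all players, per tick.

    Rows are ticks (1-based), columns Act1..Act7; every row sums to 100.
    """
    if trace.n_ticks == 0:
        raise ValueError("empty trace")
    shares = {}
    n_players = trace.action.shape[1]
    for a, label in enumerate(ACTION_LABELS, start=1):
        shares[label] = (trace.action == a).sum(axis=1) / n_players * 100.0
    return pd.DataFrame(shares, index=pd.RangeIndex(1, trace.n_ticks + 1, name="tick"))


def action_totals(trace: SimulationTrace) -> pd.Series:
    """Total number of executions of each action over the whole trace."""
    counts = np.bincount(trace.action.ravel(), minlength=8)[1:8]
    return pd.Series(counts, index=list(ACTION_LABELS))


def horizon_representativeness(
    trace_or_shares, split_tick: int
) -> HorizonSummary:
    """Compare action-share variability before and after ``split_tick``.

    For each action the standard deviation of its per-tick share is
    computed in ticks ``[1, split]`` and ``(split, end]``; similar mean
    SDs in the two windows indicate the first window already represents
    the long-run behaviour.
    """
    shares = (
        trace_or_shares
        if isinstance(trace_or_shares, pd.DataFrame)
        else action_frequency_series(trace_or_shares)
    )
    n = len(shares)
    if not 0 < split_tick < n:
        raise ValueError(f"split tick must lie strictly inside 1..{n}")
    first = shares.iloc[:split_tick]
    second = shares.iloc[split_tick:]
    per_action = pd.DataFrame(
        {"sd_first": first.std(ddof=1), "sd_second": second.std(ddof=1)}
    )
    m1 = float(per_action["sd_first"].mean())
    m2 = float(per_action["sd_second"].mean())
    rel = abs(m2 - m1) / m1 if m1 > 0 else (0.0 if m2 == 0 else float("inf"))
    return HorizonSummary(
        per_action=per_action,
        mean_sd_first=m1,
        mean_sd_second=m2,
        relative_difference=rel,
    )


def cv_stabilization(
    outcomes, tolerance: float = 0.05, window: int = 5
) -> CVStabilization:
    """Replicate-count stabilization of the outcome CV.

    ``outcomes`` is a (replicates x outcomes) table, one row per
    replicate run in seed order.  For each replicate count ``k`` the
    coefficient of variation (sample SD / mean) of every outcome over the
    first ``k`` replicates is averaged into one curve.  The stabilization
    count is the smallest ``k`` whose trailing ``window`` consecutive
    relative changes of the curve all stay below ``tolerance``; with a
    perfectly flat curve this is the window minimum, ``window + 2``.

    Outcomes with (near) zero mean have an undefined CV; they are
    excluded and reported in ``excluded_outcomes``.
    """
    table = pd.DataFrame(outcomes)
    n = len(table)
    if n < 2:
        raise ValueError("need at least two replicates")
    values = table.to_numpy(dtype=float)
    means_all = values.mean(axis=0)
    excluded = tuple(table.columns[np.abs(means_all) < 1e-12])
    keep = np.abs(means_all) >= 1e-12
    values = values[:, keep]
    ks = np.arange(2, n + 1)
    curve = []
    for k in ks:
        sub = values[:k]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(mean) < 1e-12, np.nan, sd / np.abs(mean))
        curve.append(float(np.nanmean(cv)) if np.any(~np.isnan(cv)) else np.nan)
    series = pd.Series(curve, index=pd.Index(ks, name="replicates"))
    rel_change = series.diff().abs() / series.shift(1).replace(0.0, np.nan)
    rel_change = rel_change.fillna(0.0)  # flat-at-zero counts as stable
    count = None
    for k in ks[window:]:
        recent = rel_change.loc[k - window + 1 : k]
        if len(recent) == window and bool((recent < tolerance).all()):
            count = int(k)
            break
    return CVStabilization(
        curve=series, stabilization_count=count, excluded_outcomes=excluded
    )


def _per_player_shares(trace: SimulationTrace) -> pd.DataFrame:
    """Percent of ticks each player spent in each action."""
    ticks = trace.n_ticks
    rows = []
    for j in range(trace.action.shape[1]):
        counts = np.bincount(trace.action[:, j], minlength=8)[1:8]
        rows.append(counts / ticks * 100.0)
    return pd.DataFrame(
        rows, index=pd.RangeIndex(1, 23, name="player_id"), columns=list(ACTION_LABELS)
    )


_LEVELS = ("player", "role", "team", "aggregate")


def variability_summary(
    traces_by_config: Mapping[str, Sequence[SimulationTrace]],
    level: str = "player",
) -> pd.DataFrame:
    """Mean/median/variance of action frequencies across configurations.

    For each configuration the per-player action shares (percent of
    ticks) are averaged over its replicates and grouped to the requested
    level; the statistics are then taken across configurations.  Levels
    nest: the aggregate value is the player-weighted mean of the team
    values.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {_LEVELS}")
    per_config = {}
    for name, traces in traces_by_config.items():
        if len(traces) == 0:
            raise ValueError(f"configuration {name!r} has no traces")
        shares = sum(_per_player_shares(t) for t in traces) / len(traces)
        ref = traces[0]
        if level == "player":
            grouped = shares
        elif level == "role":
            grouped = shares.groupby(pd.Index(ref.roles, name="role")).mean()
        elif level == "team":
            team = pd.Index(["A" if t == 0 else "B" for t in ref.team], name="team")
            grouped = shares.groupby(team).mean()
        else:
            grouped = shares.mean().to_frame("all").T
            grouped.index.name = "aggregate"
        per_config[name] = grouped
    stacked = pd.concat(per_config, names=["config"])
    group_level = stacked.index.names[1]
    grouped = stacked.groupby(level=group_level, sort=True)
    out = pd.concat(
        {"mean": grouped.mean(), "median": grouped.median(), "variance": grouped.var(ddof=1)},
        axis=1,
    )
    return out


def _player_track(trace: SimulationTrace, player_id: int) -> np.ndarray:
    if not 1 <= player_id <= 22:
        raise ValueError("player ids are 1..22")
    return trace.pos[:, player_id - 1, :]


def _target_track(trace: SimulationTrace, target) -> np.ndarray:
    if isinstance(target, str) and target.lower() == "ball":
        return trace.ball_pos
    return _player_track(trace, int(target))


def relative_orientation_histogram(
    trace: SimulationTrace, player_id: int, target
) -> OrientationHistogram:
    """36-class histogram of the player's relative orientation to a target.

    The relative orientation at a tick is the signed smallest angle from
    the player's heading to the bearing of the target (negative = left
    turn needed), binned into 10-degree classes.  The bearing to a
    coincident target is undefined, so ticks where the target sits at
    the player's own position (the ball at the carrier's feet) are
    excluded from the histogram.
    """
    if isinstance(target, (int, np.integer)) and int(target) == player_id:
        raise ValueError("target must differ from the player")
    me = _player_track(trace, player_id)
    them = _target_track(trace, target)
    heading = trace.heading[:, player_id - 1]
    delta = them - me
    dist = np.hypot(delta[:, 0], delta[:, 1])
    valid = dist >= 1e-9
    if not np.any(valid):
        raise ValueError("target coincides with the player at every tick")
    bearing = np.degrees(np.arctan2(delta[valid, 1], delta[valid, 0]))
    rel = (bearing - heading[valid] + 180.0) % 360.0 - 180.0
    rel = np.where(rel == -180.0, 180.0, rel)
    cls = np.floor((rel + 5.0) / 10.0).astype(int)
    cls = np.where(cls == -18, 18, cls)
    counts = np.bincount(cls + 17, minlength=36)
    shares = counts / counts.sum() * 100.0
    return OrientationHistogram(
        classes=ORIENTATION_CLASSES, shares=shares, player_id=player_id, target=target
    )


def relative_distance_summary(
    trace: SimulationTrace, player_id: int, target
) -> DistanceSummary:
    """Per-tick Euclidean distance from the player to the target."""
    if isinstance(target, (int, np.integer)) and int(target) == player_id:
        raise ValueError("target must differ from the player")
    me = _player_track(trace, player_id)
    them = _target_track(trace, target)
    delta = them - me
    series = np.hypot(delta[:, 0], delta[:, 1])
    return DistanceSummary(
        series=series,
        mean=float(series.mean()),
        min=float(series.min()),
        max=float(series.max()),
    )


def possession_matrix(events: Sequence[EventRecord]) -> PossessionMatrix:
    """Accumulate pass and possession-change events into the matrix.

    Completed passes fill the (from, to) cells; team-level possession
    changes only increment the winning team's total.
    """
    passes = np.zeros((22, 22), dtype=int)
    gains = {"A": 0, "B": 0}
    for e in events:
        if e.kind == PASS_COMPLETE:
            i, j = e.from_player - 1, e.to_player - 1
            if (i < 11) != (j < 11):
                raise DataError(
                    f"pass event between different teams: {e.from_player}->{e.to_player}"
                )
            passes[i, j] += 1
        elif e.kind == POSSESSION_CHANGE:
            gains[e.team] += 1
    return PossessionMatrix(passes=passes, team_gains=gains)


def _boxes_for(trace: SimulationTrace) -> list:
    cfg = trace.config
    fa = build_formation(cfg.formation_a, "A", cfg.pitch)
    fb = build_formation(cfg.formation_b, "B", cfg.pitch)
    state = init_match(default_roster(), fa, fb, cfg.pitch)
    return state.boxes


def role_box_occupancy(
    trace: SimulationTrace,
    formations: tuple[Formation, Formation] | None = None,
) -> pd.DataFrame:
    """Distribution of players around their role-box centres.

    Returns one row per player with the mean and SD of the distance to
    the own box centre and the fraction of ticks spent inside the box.
    """
    if formations is not None:
        boxes = []
        for i in range(22):
            formation = formations[0] if i < 11 else formations[1]
            boxes.append(formation.role_boxes[i % 11])
    else:
        boxes = _boxes_for(trace)
    rows = []
    for j, box in enumerate(boxes):
        track = trace.pos[:, j, :]
        delta = track - box.centre
        dist = np.hypot(delta[:, 0], delta[:, 1])
        inside = (
            (track[:, 0] >= box.xmin)
            & (track[:, 0] <= box.xmax)
            & (track[:, 1] >= box.ymin)
            & (track[:, 1] <= box.ymax)
        )
        rows.append(
            {
                "player_id": j + 1,
                "role": box.role_label,
                "mean_dist": float(dist.mean()),
                "sd_dist": float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
                "inside_fraction": float(inside.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("player_id")
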