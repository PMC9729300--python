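"""Tick loop, configuration presets, replicates and trace I/O.

One tick is 100 ms of simulated time and one recorded frame.  Within a
tick the 22 players act sequentially in an order shuffled by the run RNG
(asynchronous, NetLogo-`ask`-style updating): each perceives the current
world, decides, and moves or launches the ball; then the ball advances,
goals are detected, energies decay, and the frame is recorded.  A trace
is a pure function of (config, seed).

The sensitivity presets vary one factor at a time against the default:

========  ==========================================================
C1        both teams 3-5-2, man-to-man marking, energy consumption on
C2        C1 with energy consumption off
C3        C1 with team B playing 4-3-3
C4        C1 with team A playing 4-3-3
C5        C1 with both teams marking zonally
========  ==========================================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import (
    FREE_BALL,
    EnergyParams,
    KinematicParams,
    MatchState,
    default_roster,
    energy_decrement,
    init_match,
    kinematic_step,
    effective_attribute,
)
from .actions import (
    SHOT,
    ActionParams,
    BallParams,
    EventRecord,
    detect_goal_and_reset,
    launch_pass,
    launch_shot,
    plan_action,
    select_pass_target,
    update_ball,
)
from .decision import Action, DecisionParams, build_context, decide_action, rank_defenders
from .environment import Formation, PitchConfig, build_formation

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "PresetError",
    "TraceParseError",
    "PRESET_NAMES",
    "preset",
    "run",
    "run_replicates",
    "write_trace",
    "read_trace",
]

PRESET_NAMES = ("C1", "C2", "C3", "C4", "C5")

_TEAM_LETTER = ("A", "B")


class PresetError(ValueError):
    """Unknown configuration preset."""


class TraceParseError(ValueError):
    """Malformed trace file."""


@dataclass
class SimulationConfig:
    """Full parameterization of one run."""

    ticks: int = 5000
    seed: int = 0
    formation_a: str = "3-5-2"
    formation_b: str = "3-5-2"
    marking_a: str = "man-to-man"
    marking_b: str = "man-to-man"
    energy_consumption: bool = True
    pitch: PitchConfig = field(default_factory=PitchConfig)
    decision: DecisionParams = field(default_factory=DecisionParams)
    kinematics: KinematicParams = field(default_factory=KinematicParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    ball: BallParams = field(default_factory=BallParams)
    actions: ActionParams = field(default_factory=ActionParams)

    def __post_init__(self) -> None:
        if self.ticks < 1:
            raise ValueError("ticks must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key, typ in (
            ("pitch", PitchConfig),
            ("decision", DecisionParams),
            ("kinematics", KinematicParams),
            ("energy", EnergyParams),
            ("ball", BallParams),
            ("actions", ActionParams),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)


def preset(name: str, **overrides) -> SimulationConfig:
    """One of the five one-factor-at-a-time configurations C1-C5."""
    if name not in PRESET_NAMES:
        raise PresetError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    config = SimulationConfig()
    if name == "C2":
        config.energy_consumption = False
    elif name == "C3":
        config.formation_b = "4-3-3"
    elif name == "C4":
        config.formation_a = "4-3-3"
    elif name == "C5":
        config.marking_a = "zonal"
        config.marking_b = "zonal"
    for key, value in overrides.items():
        if not hasattr(config, key):
            raise PresetError(f"unknown configuration field {key!r}")
        setattr(config, key, value)
    return config


@dataclass
class SimulationTrace:
    """Per-tick positions, headings, energies and actions of the 22
    players, the ball track, the event log and the generating config."""

    config: SimulationConfig
    roles: list[str]
    team: np.ndarray  # (22,) 0=A 1=B
    pos: np.ndarray  # (T, 22, 2)
    heading: np.ndarray  # (T, 22)
    energy: np.ndarray  # (T, 22)
    action: np.ndarray  # (T, 22) int8, values 1..7
    ball_pos: np.ndarray  # (T, 2)
    possessor: np.ndarray  # (T,) player index or FREE_BALL
    events: list[EventRecord] = field(default_factory=list)

    @property
    def n_ticks(self) -> int:
        return self.pos.shape[0]

    def players_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per player per tick."""
        ticks = np.repeat(np.arange(1, self.n_ticks + 1), 22)
        ids = np.tile(np.arange(1, 23), self.n_ticks)
        return pd.DataFrame(
            {
                "tick": ticks,
                "player_id": ids,
                "team": np.tile(np.array([_TEAM_LETTER[t] for t in self.team]), self.n_ticks),
                "role": np.tile(np.array(self.roles), self.n_ticks),
                "x": self.pos[:, :, 0].ravel(),
                "y": self.pos[:, :, 1].ravel(),
                "heading": self.heading.ravel(),
                "energy": self.energy.ravel(),
                "action": self.action.ravel(),
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tick": e.tick,
                    "kind": e.kind,
                    "from": e.from_player,
                    "to": e.to_player,
                    "team": e.team,
                }
                for e in self.events
            ],
            columns=["tick", "kind", "from", "to", "team"],
        )


def _build_state(config: SimulationConfig, rng: np.random.Generator) -> MatchState:
    formation_a = build_formation(config.formation_a, "A", config.pitch)
    formation_b = build_formation(config.formation_b, "B", config.pitch)
    state = init_match(default_roster(), formation_a, formation_b, config.pitch, rng=rng)
    state.marking_plan = (config.marking_a, config.marking_b)
    return state


def run(config: SimulationConfig) -> SimulationTrace:
    """Simulate one match of ``config.ticks`` ticks.

    The trace is reproducible bit-for-bit from (config, seed): all
    randomness (player update order, random-walk targets, contest
    tie-breaks, shot aim) flows from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    state = _build_state(config, rng)
    energy_params = replace(config.energy, enabled=config.energy_consumption)
    kin = config.kinematics
    dp = config.decision
    bp = config.ball
    ap = config.actions

    ticks = config.ticks
    trace_pos = np.empty((ticks, 22, 2))
    trace_heading = np.empty((ticks, 22))
    trace_energy = np.empty((ticks, 22))
    trace_action = np.empty((ticks, 22), dtype=np.int8)
    trace_ball = np.empty((ticks, 2))
    trace_possessor = np.empty(ticks, dtype=np.int8)
    events: list[EventRecord] = []

    members_a = state.team_indices(0)
    members_b = state.team_indices(1)

    for tick in range(1, ticks + 1):
        pos0 = state.pos.copy()
        ball0 = state.ball.position.copy()
        deltas = pos0 - ball0
        dist_ball0 = np.hypot(deltas[:, 0], deltas[:, 1])
        defenders = {}
        for team, members in ((0, members_a), (1, members_b)):
            order = np.lexsort((members, dist_ball0[members]))
            defenders[team] = (int(members[order[0]]), int(members[order[1]]))
        actions_t = np.zeros(22, dtype=np.int8)
        for idx in rng.permutation(22):
            idx = int(idx)
            fd, sd = defenders[int(state.team[idx])]
            ctx = build_context(
                state,
                idx,
                dp,
                energy_params,
                first_defender=fd,
                second_defender=sd,
                max_step=kin.max_step,
            )
            act = decide_action(ctx)
            target, command = plan_action(state, idx, act, dp, ap, rng, positions=pos0)
            if command == "pass":
                receiver = select_pass_target(state, idx)
                if receiver is None:
                    # no forward option: fall back to carrying
                    act = Action.ACT4
                    target, command = plan_action(state, idx, act, dp, ap, rng, positions=pos0)
                else:
                    launch_pass(state, idx, receiver, bp)
            if command == "shoot":
                events.append(
                    EventRecord(
                        tick=tick,
                        kind=SHOT,
                        from_player=idx + 1,
                        to_player=None,
                        team=_TEAM_LETTER[int(state.team[idx])],
                    )
                )
                launch_shot(state, idx, bp, rng, energy_params)
            elif command != "pass":
                pace = effective_attribute(
                    float(state.pace[idx]), float(state.energy[idx]), energy_params
                )
                state.pos[idx], state.heading[idx] = kinematic_step(
                    state.pos[idx], float(state.heading[idx]), target, pace,
                    state.pitch, kin,
                )
            actions_t[idx] = int(act)

        moved = state.pos - pos0
        step_lengths = np.hypot(moved[:, 0], moved[:, 1])
        update_ball(state, bp, pressing=actions_t == 3, events=events, tick=tick,
                    rng=rng, energy_params=energy_params)
        detect_goal_and_reset(state, events, tick)
        if energy_params.enabled:
            state.energy = np.maximum(
                0.0,
                state.energy - energy_decrement(state.stamina, step_lengths, energy_params),
            )

        t = tick - 1
        trace_pos[t] = state.pos
        trace_heading[t] = state.heading
        trace_energy[t] = state.energy
        trace_action[t] = actions_t
        trace_ball[t] = state.ball.position
        trace_possessor[t] = state.ball.possessor

    return SimulationTrace(
        config=config,
        roles=list(state.roles),
        team=state.team.copy(),
        pos=trace_pos,
        heading=trace_heading,
        energy=trace_energy,
        action=trace_action,
        ball_pos=trace_ball,
        possessor=trace_possessor,
        events=events,
    )


def run_replicates(
    config: SimulationConfig, n: int, base_seed: int
) -> list[SimulationTrace]:
    """``n`` independent replicates seeded ``base_seed .. base_seed+n-1``."""
    if n < 1:
        raise ValueError("need at least one replicate")
    traces = []
    for i in range(n):
        traces.append(run(replace(config, seed=base_seed + i)))
    return traces


# ---------------------------------------------------------------------------
# trace I/O: delimited text plus an events table and a JSON config sidecar

_TRACE_COLUMNS = ["tick", "player_id", "team", "role", "x", "y", "heading", "energy", "action"]


def _base_path(path) -> Path:
    path = Path(path)
    return path.with_suffix("") if path.suffix == ".csv" else path


def write_trace(trace: SimulationTrace, path) -> Path:
    """Write ``<base>.csv`` (frames), ``<base>.events.csv`` and
    ``<base>.config.json``.

    Frame rows hold one player per tick plus one ball row per tick
    (``player_id == "ball"``, whose ``action`` column carries the
    possessor id, empty when the ball is free).  Positions, headings and
    energies are rounded to 4 decimals.
    """
    base = _base_path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    frames = trace.players_frame()
    frames["action"] = "Act" + frames["action"].astype(str)
    ball_rows = pd.DataFrame(
        {
            "tick": np.arange(1, trace.n_ticks + 1),
            "player_id": "ball",
            "team": "",
            "role": "",
            "x": trace.ball_pos[:, 0],
            "y": trace.ball_pos[:, 1],
            "heading": np.nan,
            "energy": np.nan,
            "action": [
                "" if p == FREE_BALL else str(int(p) + 1) for p in trace.possessor
            ],
        }
    )
    combined = pd.concat([frames, ball_rows], ignore_index=True)
    combined = combined.sort_values(
        ["tick", "player_id"],
        key=lambda s: s.map(lambda v: 23 if v == "ball" else v) if s.name == "player_id" else s,
    )
    for col in ("x", "y", "heading", "energy"):
        combined[col] = combined[col].round(4)
    csv_path = base.with_suffix(".csv")
    combined.to_csv(csv_path, index=False, columns=_TRACE_COLUMNS)
    trace.events_frame().to_csv(base.parent / f"{base.name}.events.csv", index=False)
    with open(base.parent / f"{base.name}.config.json", "w") as fh:
        json.dump(trace.config.to_dict(), fh, indent=1)
    return csv_path


def read_trace(path) -> SimulationTrace:
    """Read a trace written by :func:`write_trace`.

    Raises :class:`TraceParseError` naming the missing column or the
    offending line for malformed input.
    """
    base = _base_path(path)
    csv_path = base.with_suffix(".csv")
    try:
        frame = pd.read_csv(csv_path, dtype={"player_id": str, "action": str})
    except pd.errors.ParserError as exc:
        raise TraceParseError(f"{csv_path}: {exc}") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise TraceParseError(f"{csv_path}: missing column(s) {', '.join(missing)}")

    config_path = base.parent / f"{base.name}.config.json"
    if config_path.exists():
        with open(config_path) as fh:
            config = SimulationConfig.from_dict(json.load(fh))
    else:
        config = SimulationConfig()

    players = frame[frame["player_id"] != "ball"].copy()
    balls = frame[frame["player_id"] == "ball"]
    players["player_id"] = players["player_id"].astype(int)
    ticks = int(frame["tick"].max())
    if len(players) != 22 * ticks or len(balls) != ticks:
        raise TraceParseError(
            f"{csv_path}: expected {22 * ticks} player rows and {ticks} ball rows, "
            f"got {len(players)} and {len(balls)} (truncated file?)"
        )
    players = players.sort_values(["tick", "player_id"])
    balls = balls.sort_values("tick")
    try:
        action = (
            players["action"].str.removeprefix("Act").astype(np.int8).to_numpy()
        )
    except ValueError as exc:
        raise TraceParseError(f"{csv_path}: malformed action column: {exc}") from exc
    first = players[players["tick"] == 1]
    possessor = np.array(
        [FREE_BALL if pd.isna(a) or a == "" else int(a) - 1 for a in balls["action"]],
        dtype=np.int8,
    )
    trace = SimulationTrace(
        config=config,
        roles=list(first["role"]),
        team=np.array([0 if t == "A" else 1 for t in first["team"]], dtype=np.int8),
        pos=np.stack(
            [
                players["x"].to_numpy().reshape(ticks, 22),
                players["y"].to_numpy().reshape(ticks, 22),
            ],
            axis=-1,
        ),
        heading=players["heading"].to_numpy().reshape(ticks, 22),
        energy=players["energy"].to_numpy().reshape(ticks, 22),
        action=action.reshape(ticks, 22),
        ball_pos=np.column_stack([balls["x"].to_numpy(), balls["y"].to_numpy()]),
        possessor=possessor,
        events=[],
    )
    events_path = base.parent / f"{base.name}.events.csv"
    if events_path.exists():
        edf = pd.read_csv(events_path)
        trace.events = [
            EventRecord(
                tick=int(r["tick"]),
                kind=str(r["kind"]),
                from_player=None if pd.isna(r["from"]) else int(r["from"]),
                to_player=None if pd.isna(r["to"]) else int(r["to"]),
                team=str(r["team"]),
            )
            for _, r in edf.iterrows()
        ]
    return trace
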