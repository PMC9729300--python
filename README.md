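# footsim

A reactive agent-based simulator of football-player movement, with the
verification/validation toolkit used to accredit it.

Twenty-two point vector-agents move on a 110 m × 60 m pitch in discrete
100 ms ticks. Each player carries a small set of endogenous abilities on a
0–100 scale — energy, stamina, pace, shooting, agility, teamwork — and is
spatially constrained by the rectangular *role-box* of its tactical role;
eleven role-boxes make a formation (3-5-2, 4-4-2 or 4-3-3). The ball is a
passive actor: carried by a possessor, or flying under friction until
intercepted.

Players are *purely reactive*: the movement policy is a memoryless map
`m : S → F → A` from the perception scenario
`S = {opponent has ball, no one, me, teammate}` through a handful of causal
factors `F` (ball and goal distances, opponents in the corridor to goal,
role-box membership, own abilities) to one of seven actions `A`:

| action | behaviour |
|---|---|
| Act1 | move randomly inside the role-box |
| Act2 | mark the nearest opponent (goalkeepers interpose on the ball–goal segment) |
| Act3 | get possession of the ball (only the two closest defenders may press) |
| Act4 | carry the ball toward the opponent goal |
| Act5 | pass the ball (forward only) |
| Act6 | shoot the ball / defensive clearance |
| Act7 | open up space inside the role-box |

Kinematics are attribute-driven: the per-tick step is capped at
1 m × (effective pace / 100) with at most a 180° turn; energy drains with
distance covered and low stamina, and the effective value of every other
attribute shrinks linearly with the energy level.

The package is aimed at researchers studying agent-based movement models:
it ships the one-factor-at-a-time sensitivity presets C1–C5 (default;
no energy consumption; either team switched to 4-3-3; zonal marking) and
the validation statistics — per-tick action-frequency shares, horizon
representativeness, replicate stabilization by coefficient of variation,
player/role/team/aggregate variability summaries, dyadic relative
orientation (36 ten-degree classes) and distance, pass/possession
matrices, and role-box occupancy.

## Worked example

```python
import footsim as fs
from footsim import analytics

config = fs.preset("C1", ticks=5000, seed=42)   # default configuration
trace = fs.run(config)                           # 500 simulated seconds

shares = analytics.action_frequency_series(trace).mean()
hist = analytics.relative_orientation_histogram(trace, 10, "ball")
matrix = analytics.possession_matrix(trace.events)
print(shares.round(1))
print(f"Player 10 faces the ball (class 0): {hist.share(0):.1f}% of ticks")
print(f"completed passes: {matrix.total_passes}, team gains: {matrix.team_gains}")
```

prints

```
Act1    54.0
Act2     2.8
Act3    12.3
Act4     2.6
Act5     0.2
Act6     0.1
Act7    27.9
Player 10 faces the ball (class 0): 17.6% of ticks
completed passes: 135, team gains: {'A': 91, 'B': 91}
```

Off the ball, players spend most ticks roaming their role-box (Act1) or
opening space while a teammate carries (Act7); pressing (Act3) is limited
to the two nearest defenders, and the on-ball actions (Act4–Act6) are
rare because only one of 22 players holds the ball at a time. Player 10 —
the liveliest forward — faces the ball about 17% of the time, and the
possession-gain counts are team-level tallies of tackles and
interceptions.

The same run is available from a shell:

```sh
footsim run --preset C1 --ticks 5000 --seed 42 --out trace.csv
footsim analyze --trace trace.csv --report orientation --player 10 --target ball
footsim replicates --preset C1 -n 20 --base-seed 100 --out-dir runs/
```

Traces are plain CSV (`tick, player_id, team, role, x, y, heading,
energy, action`, with ball rows as `player_id=ball`) plus an event log
and a JSON config sidecar, and round-trip through
`footsim.write_trace` / `footsim.read_trace`.

## Documentation

`docs/methods.md` describes the model assumptions, every tunable
parameter with its default and rationale, the numerical conventions, and
the known limitations of the simulator.
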