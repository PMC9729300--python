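# Model and methods

## Overview

`footsim` simulates the movement decision-making of 22 football players
as purely reactive point vector-agents on a continuous 110 m × 60 m
pitch, advanced in discrete 100 ms ticks. The design separates three
orders of movement causes: the players' own attributes (zero order), the
contextual actors — pitch, goals, role-boxes, ball (first order) — and
the other autonomous players (second order). The package exists to study
how manipulating each order changes the emergent movement patterns, not
to reproduce any empirical match: no step of the pipeline is calibrated
against real tracking data.

## Agents and attributes

Each player carries six 0–100 attributes (the packaged roster in
`data/roster.csv`): a dynamic **energy** plus static bases **stamina,
pace, shooting, agility, teamwork**. Energy drains every tick by

```
Δe = base_rate · (1 + (100 − stamina)/100) · (0.5 + step_length)
```

with `base_rate = 0.005` per tick, floored at zero. The constant is
chosen so energy declines visibly — tens of points — over the standard
5000-tick horizon; the functional form (linear in step length, inversely
modulated by stamina, with a half-cost idle term) is the package's own,
as only the qualitative behaviour is prescribed. The *effective* value
of every static attribute is scaled linearly with energy,

```
effective = base · (floor + (1 − floor) · energy/100),   floor = 0.5
```

so a fully exhausted player retains half of each ability. Configuration
C2 disables energy consumption entirely.

## Kinematics

Per tick a player may step at most `1 m × effective_pace/100` toward its
current target and turn at most 180° (the turn cap never binds for a
smallest-angle heading change; it is kept as an explicit invariant).
Headings follow the realised displacement and are unchanged when the
player holds position. Positions are clamped to the pitch. The 0.5 m
patch grid exists only for rasterization parity with grid-based
implementations; all simulation geometry is continuous.

After a goal, players are repositioned at their role-box centres for the
conceding team's kickoff. This repositioning is deliberately not a
kinematic step; the analytics extractors (`step_lengths`,
`heading_changes`) exclude those transitions when checking the per-tick
bounds.

## The decision policy

Every player, every tick, classifies the world by *who possesses the
ball?* and selects exactly one of seven actions through fixed
thresholds (all configurable in `DecisionParams`):

| parameter | default | meaning |
|---|---|---|
| `ball_close` | 15 m | "the ball is close" |
| `goal_close` | 20 m | "close to a goal" |
| `opponent_close` | 5 m | "an opponent is pressing me" |
| `corridor_width` | 4 m | corridor for "opponents between me and the goal" |
| `pressing_range` | 20 m | how far an eligible presser will chase a held ball |

The mapping:

* **Opponent has the ball** — press (Act3) if the player is the 1st or
  2nd defender (the two team members closest to the ball; ties break to
  the lower id) and the ball is within pressing range; otherwise mark
  (Act2) when the ball is close, else roam (Act1).
* **No one has the ball** — the 1st/2nd defenders chase (Act3) with no
  range cap, so a dead ball is always eventually collected; everyone
  else marks or roams by ball distance.
* **I have the ball** — a shooting chance is taken first (Act6): within
  `goal_close` of the opponent goal with fewer than two opponents in the
  corridor; goalkeepers and defenders also clear (Act6) when pressed
  within `opponent_close` near their own goal. Otherwise, if carrying
  would leave the role-box the player passes (Act5); with a clear
  corridor — or one opponent but dribbling above passing — the player
  carries (Act4); otherwise passes (Act5).
* **A teammate has the ball** — open space (Act7) inside the role-box.

Dribbling skill is the effective *agility* and passing skill the
effective *teamwork*; the attribute roster has no dedicated
dribbling and passing columns, so this mapping is explicit and configurable.
The row order of the reference decision table does not state precedence inside
the on-ball scenario; evaluating the shooting clause first encodes "a
player in range shoots". The no-possessor branch of the reference table is ambiguous;
the reconstruction above (ranked defenders
chase, others mark/roam) is the package's reading and is pinned by an
exhaustive decision-table test against an independently hand-coded
oracle.

The policy is memoryless and total: identical contexts give identical
actions, and at most two players per team can ever press (Act3) because
only ranked defenders may.

Marking plans: **man-to-man** fixes the assignment at init (player *i*
marks the opponent with the same within-team index); **zonal** marks the
opponent currently nearest the player's role-box centre.

## Action execution and ball mechanics

Movement targets: Act1 draws a uniform point in the role-box (a fresh
draw each tick gives a bounded random walk); Act2 heads for the marked
opponent (goalkeepers instead hold a point `gk_guard_distance = 6 m` out
from the own goal centre along the ball–goal segment); Act3 heads for
the ball; Act4 for the opponent goal centre; Act7 for the role-box grid
point (2 m spacing by default, 0.5 m reproduces the exhaustive search)
farthest from the nearest opponent. Act5/Act6 hold position and launch
the ball.

Ball parameters (`BallParams`): pass speed 3 m/tick, shot speed
5 m/tick, friction 0.9 per tick, interception and possession radii 1 m,
rest threshold 0.25 m/tick. All of these are package defaults, chosen to give passes a ~27 m range and
shots a goal-reaching range from the shooting threshold distance.

A flying ball is intercepted by any player within 1 m of the discretized
flight segment, with two exceptions: the launcher, and any player who was
already within the possession radius of the launch point — the presser
the passer just played past. Without the second rule every pass is
blocked at the launch tick by the adjacent presser and the match
degenerates into a one-tick possession ping-pong. Pass receivers must be
strictly ahead of the passer (no backward passes) and within the ball's
friction-limited range; when no such teammate exists the player falls
back to carrying. Possession contests (tackles on a carrier by adjacent
pressers, scrambles for a loose ball) go to the highest effective
agility, exact ties uniformly at random.

A completed pass is credited only when the first touch after a pass
launch is by a teammate who was strictly closer to the opponent goal
line at launch; a touch by anyone else is a plain possession event, and
a change of team emits a team-level possession-change record (no player
pair, matching how possession matrices aggregate team gains). Shots aim
at a uniform point of the goal mouth plus Gaussian noise with standard
deviation `3 m × (100 − effective_shooting)/100`; a goal is a flight
segment crossing the goal line inside the 7.32 m mouth. There are no
throw-ins, corners, fouls or substitutions: the boundary simply stops
the ball.

## Scheduling and reproducibility

Within a tick, players act sequentially in an order reshuffled by the
run RNG (asynchronous, NetLogo-`ask`-style updating; the original model's
scheduling is not specified). Defender ranks and perception snapshots are
taken at the start of the tick; movement updates in place. Then the ball
advances, goals are detected, energies decay, and the frame is recorded.
A trace is a pure function of (config, seed); replicate *i* of a batch
uses `base_seed + i`. Everything random — update order, random-walk
targets, tie-breaks, shot aim — draws from the single seeded generator.

## Role-boxes and formations

Role-box rectangles are **assumptions, not reference values**. The shipped YAML templates give the
goalkeeper the penalty-area region and split defender/midfielder/forward
bands across the pitch thirds with overlaps; side B is the point
reflection of side A through the pitch centre. Rectangles are closed
(boundary counts as inside) to avoid oscillation at edges. The ordering
of roles — goalkeeper, defenders, midfielders, forwards, each
right-to-left — assigns player 10 a forward box under 3-5-2, consistent
with that player being the most active agent. The configuration label "4-4-3" is treated as 4-3-3 (the
only offered three-forward option); `build_formation("4-4-3")` is an
error.

## Validation toolkit

* **Action-frequency shares** per tick sum to 100% across the seven
  actions; horizon representativeness compares the mean per-action share
  SD before and after a split tick.
* **Replicate stabilization**: per replicate the seven per-action total
  frequencies form the outcome vector; the aggregated coefficient of
  variation over the first *k* replicates is tracked as *k* grows, and
  the stabilization count is the smallest *k* whose trailing five
  relative curve changes all stay below 5% (tolerance and window
  configurable). On a perfectly flat curve this yields the window
  minimum, `window + 2`.
* **Dyadic statistics**: the relative orientation to a target is the
  signed smallest angle from heading to bearing (negative = left turn),
  binned into 36 half-open 10° classes `[k−5, k+5)`. Ticks where the
  target coincides with the player — the ball at the carrier's feet —
  have no defined bearing and are excluded from the histogram.
* **Possession matrix**: 22 × 22 completed-pass counts plus team-level
  possession-gain totals; its grand total equals the pass event count by
  construction.
* **Role-box occupancy**: per player, mean/SD distance to the own box
  centre and the inside fraction.

## Problem sizes used by the shipped checks

The default test suite verifies the full-scale kinematic bounds on one
5000-tick run and the stochastic references at reduced scale (30 × 1200
ticks for stabilization, 6 × 2500 ticks per configuration for the
orientation references, 3 × 1000 ticks per configuration for the
sensitivity ordering) so the whole suite stays fast;
`scripts/acceptance.py` reproduces the full-scale study (30 and 20
replicates of 5000 ticks).

## Limitations

* The simulator is deliberately data-poor: attribute roster, thresholds,
  role-box extents and ball physics are modelling assumptions. Passing
  the shipped checks shows internal consistency and qualitative
  agreement with the reference validation summaries, not fidelity to
  real matches.
* Mental and psychological states, set pieces, substitutions and
  out-of-bounds events are out of scope by design.
* Goal frequency is far above realistic rates (shots are cheap and
  defences thin near the mouth); analyses that depend on restart
  frequency should treat goal counts as model artefacts.
* Role zones are hard axis-aligned rectangles; fuzzy, dynamic or
  data-driven zones are future work.
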