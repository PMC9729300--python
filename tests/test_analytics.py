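import numpy as np
import pandas as pd
import pytest

from footsim import analytics as an
from footsim.actions import EventRecord

from conftest import make_toy_trace


class TestActionFrequencySeries:
    def test_toy_counts_by_hand(self):
        # 4 players, 3 ticks with hand-set actions
        action = [[1, 1, 2, 7], [3, 3, 3, 3], [1, 2, 4, 7]]
        trace = make_toy_trace(np.zeros((3, 4, 2)), action=action)
        shares = an.action_frequency_series(trace)
        assert shares.loc[1, "Act1"] == pytest.approx(50.0)
        assert shares.loc[1, "Act2"] == pytest.approx(25.0)
        assert shares.loc[2, "Act3"] == pytest.approx(100.0)
        assert shares.loc[3, "Act4"] == pytest.approx(25.0)

    def test_shares_sum_to_100_each_tick(self, c1_trace):
        shares = an.action_frequency_series(c1_trace)
        assert np.allclose(shares.sum(axis=1), 100.0)

    def test_empty_trace_rejected(self):
        trace = make_toy_trace(np.zeros((0, 4, 2)))
        with pytest.raises(ValueError):
            an.action_frequency_series(trace)


class TestHorizonRepresentativeness:
    def test_identical_halves_have_zero_difference(self):
        half = np.array([[1, 2], [3, 4], [1, 7], [2, 2]], dtype=np.int8)
        trace = make_toy_trace(
            np.zeros((8, 2, 2)), action=np.vstack([half, half])
        )
        summary = an.horizon_representativeness(trace, split_tick=4)
        assert summary.mean_sd_first == pytest.approx(summary.mean_sd_second)
        assert summary.relative_difference == pytest.approx(0.0)

    def test_constant_series_has_zero_sd(self):
        trace = make_toy_trace(np.zeros((10, 3, 2)))  # everyone Act1 always
        summary = an.horizon_representativeness(trace, split_tick=5)
        assert summary.mean_sd_first == 0.0
        assert summary.mean_sd_second == 0.0

    def test_hand_computed_sds(self):
        # one player alternating Act1/Act2 in the first window only
        action = np.array([[1], [2], [1], [2], [1], [1], [1], [1]], dtype=np.int8)
        trace = make_toy_trace(np.zeros((8, 1, 2)), action=action)
        summary = an.horizon_representativeness(trace, split_tick=4)
        # Act1 share series first window: 100, 0, 100, 0 -> sd = 57.735
        assert summary.per_action.loc["Act1", "sd_first"] == pytest.approx(57.735, abs=1e-3)
        assert summary.per_action.loc["Act1", "sd_second"] == 0.0

    def test_split_out_of_range_rejected(self, c1_trace):
        with pytest.raises(ValueError):
            an.horizon_representativeness(c1_trace, split_tick=c1_trace.n_ticks)


class TestCVStabilization:
    def test_hand_computed_cv(self):
        result = an.cv_stabilization(pd.DataFrame({"x": [8.0, 12.0]}), window=0)
        # sd = 2*sqrt(2), mean = 10
        assert result.curve.loc[2] == pytest.approx(np.sqrt(8) / 10.0)

    def test_identical_replicates_stabilize_at_the_window_minimum(self):
        outcomes = pd.DataFrame(np.tile([5.0, 9.0, 2.0], (12, 1)))
        result = an.cv_stabilization(outcomes, tolerance=0.05, window=5)
        assert np.allclose(result.curve, 0.0)
        assert result.stabilization_count == 7  # window + 2

    def test_zero_mean_outcome_is_flagged_and_excluded(self):
        outcomes = pd.DataFrame({"live": [4.0, 6.0, 5.0], "dead": [0.0, 0.0, 0.0]})
        result = an.cv_stabilization(outcomes, window=0)
        assert result.excluded_outcomes == ("dead",)
        assert np.isfinite(result.curve).all()

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            an.cv_stabilization(pd.DataFrame({"x": [1.0]}))

    def test_looser_tolerance_stabilizes_no_later(self):
        rng = np.random.default_rng(8)
        outcomes = pd.DataFrame(rng.normal(50, 5, size=(25, 4)))
        tight = an.cv_stabilization(outcomes, tolerance=0.02)
        loose = an.cv_stabilization(outcomes, tolerance=0.2)
        if tight.stabilization_count is not None:
            assert loose.stabilization_count <= tight.stabilization_count


class TestVariabilitySummary:
    def _trace_pair(self):
        rng = np.random.default_rng(2)
        team = np.array([0] * 11 + [1] * 11)
        roles = ["G"] + ["D"] * 4 + ["M"] * 4 + ["F"] * 2
        roles = roles + roles
        t1 = make_toy_trace(
            np.zeros((50, 22, 2)),
            action=rng.integers(1, 8, size=(50, 22)),
            team=team,
            roles=roles,
        )
        t2 = make_toy_trace(
            np.zeros((50, 22, 2)),
            action=rng.integers(1, 8, size=(50, 22)),
            team=team,
            roles=roles,
        )
        return t1, t2

    def test_identical_configurations_have_zero_variance(self):
        t1, _ = self._trace_pair()
        summary = an.variability_summary({"C1": [t1], "C2": [t1], "C3": [t1]}, "player")
        assert np.allclose(summary["variance"].to_numpy(), 0.0)

    def test_aggregate_is_the_player_weighted_team_mean(self):
        t1, t2 = self._trace_pair()
        by_team = an.variability_summary({"C1": [t1], "C2": [t2]}, "team")
        agg = an.variability_summary({"C1": [t1], "C2": [t2]}, "aggregate")
        # teams have 11 players each, so the aggregate mean is the plain mean
        assert np.allclose(
            agg["mean"].to_numpy().ravel(),
            by_team["mean"].mean(axis=0).to_numpy(),
        )

    def test_hand_computed_player_mean(self):
        action = np.full((10, 22), 7, dtype=np.int8)
        action[:5, 0] = 1  # player 1: half Act1, half Act7
        t1 = make_toy_trace(np.zeros((10, 22, 2)), action=action)
        summary = an.variability_summary({"C1": [t1]}, "player")
        assert summary.loc[1, ("mean", "Act1")] == pytest.approx(50.0)
        assert summary.loc[1, ("mean", "Act7")] == pytest.approx(50.0)
        assert summary.loc[2, ("mean", "Act7")] == pytest.approx(100.0)

    def test_unknown_level_rejected(self):
        t1, _ = self._trace_pair()
        with pytest.raises(ValueError):
            an.variability_summary({"C1": [t1]}, "galaxy")


class TestOrientationHistogram:
    def test_heading_straight_at_the_target_is_class_zero(self):
        pos = np.zeros((20, 1, 2))
        ball = np.tile([10.0, 0.0], (20, 1))
        trace = make_toy_trace(pos, ball_pos=ball)  # heading 0 = toward +x
        hist = an.relative_orientation_histogram(trace, 1, "ball")
        assert hist.share(0) == pytest.approx(100.0)

    def test_minus_ten_degrees_falls_in_class_minus_ten(self):
        # target 10 degrees clockwise (to the right is positive bearing change)
        pos = np.zeros((10, 1, 2))
        bearing = np.deg2rad(-10.0)
        ball = np.tile([10 * np.cos(bearing), 10 * np.sin(bearing)], (10, 1))
        trace = make_toy_trace(pos, ball_pos=ball)
        hist = an.relative_orientation_histogram(trace, 1, "ball")
        assert hist.share(-10) == pytest.approx(100.0)

    def test_half_open_class_boundaries(self):
        # classes cover [k-5, k+5): -5 opens class 0, just below it is -10
        for angle, expected in ((-5.0, 0), (-5.0 - 1e-6, -10), (4.999, 0), (5.0, 10)):
            pos = np.zeros((4, 1, 2))
            bearing = np.deg2rad(angle)
            ball = np.tile([np.cos(bearing), np.sin(bearing)], (4, 1))
            trace = make_toy_trace(pos, ball_pos=ball)
            hist = an.relative_orientation_histogram(trace, 1, "ball")
            assert hist.share(expected) == pytest.approx(100.0)

    def test_uniform_headings_spread_evenly(self):
        rng = np.random.default_rng(4)
        n = 40000
        pos = np.zeros((n, 1, 2))
        heading = rng.uniform(-180, 180, size=(n, 1))
        ball = np.tile([10.0, 0.0], (n, 1))
        trace = make_toy_trace(pos, heading=heading, ball_pos=ball)
        hist = an.relative_orientation_histogram(trace, 1, "ball")
        assert np.all(np.abs(hist.shares - 100.0 / 36.0) < 0.7)

    def test_shares_sum_to_100(self, c1_trace):
        hist = an.relative_orientation_histogram(c1_trace, 10, "ball")
        assert float(hist.shares.sum()) == pytest.approx(100.0)
        assert len(hist.classes) == 36

    def test_coincident_target_everywhere_rejected(self):
        pos = np.zeros((5, 2, 2))
        trace = make_toy_trace(pos)
        with pytest.raises(ValueError):
            an.relative_orientation_histogram(trace, 1, 2)

    def test_self_target_rejected(self, c1_trace):
        with pytest.raises(ValueError):
            an.relative_orientation_histogram(c1_trace, 10, 10)


class TestDistanceSummary:
    def test_static_pair_at_constant_distance(self):
        pos = np.zeros((15, 2, 2))
        pos[:, 1, 0] = 7.0
        trace = make_toy_trace(pos)
        summary = an.relative_distance_summary(trace, 1, 2)
        assert np.allclose(summary.series, 7.0)
        assert summary.mean == summary.min == summary.max == 7.0

    def test_symmetry_in_the_pair(self, c1_trace):
        forward = an.relative_distance_summary(c1_trace, 10, 17)
        backward = an.relative_distance_summary(c1_trace, 17, 10)
        assert np.allclose(forward.series, backward.series)

    def test_hand_computed_mean(self):
        pos = np.zeros((2, 2, 2))
        pos[0, 1] = (3.0, 4.0)  # 5 m
        pos[1, 1] = (0.0, 1.0)  # 1 m
        trace = make_toy_trace(pos)
        summary = an.relative_distance_summary(trace, 1, 2)
        assert summary.mean == pytest.approx(3.0)


class TestPossessionMatrix:
    def test_toy_event_log_filled_by_hand(self):
        events = [
            EventRecord(1, "pass_complete", 5, 9, "A"),
            EventRecord(4, "pass_complete", 5, 9, "A"),
            EventRecord(9, "pass_complete", 9, 10, "A"),
            EventRecord(12, "pass_complete", 15, 20, "B"),
            EventRecord(15, "possession_change_between_teams", None, None, "B"),
            EventRecord(19, "possession_change_between_teams", None, None, "A"),
            EventRecord(21, "possession_change_between_teams", None, None, "B"),
        ]
        matrix = an.possession_matrix(events)
        assert matrix.passes[4, 8] == 2
        assert matrix.passes[8, 9] == 1
        assert matrix.passes[14, 19] == 1
        assert matrix.total_passes == 4
        assert matrix.team_gains == {"A": 1, "B": 2}

    def test_single_pass(self):
        matrix = an.possession_matrix([EventRecord(1, "pass_complete", 5, 9, "A")])
        assert matrix.passes[4, 8] == 1
        assert matrix.passes.sum() == 1

    def test_cross_team_pass_rejected(self):
        with pytest.raises(an.DataError):
            an.possession_matrix([EventRecord(1, "pass_complete", 5, 15, "A")])

    def test_matrix_total_matches_event_count_on_a_run(self, c1_trace):
        matrix = an.possession_matrix(c1_trace.events)
        n_passes = sum(1 for e in c1_trace.events if e.kind == "pass_complete")
        assert matrix.total_passes == n_passes


class TestRoleBoxOccupancy:
    def test_player_parked_at_its_centre(self, formation_a, formation_b):
        centres = np.array(
            [b.centre for b in formation_a.role_boxes]
            + [b.centre for b in formation_b.role_boxes]
        )
        pos = np.tile(centres, (6, 1, 1))
        trace = make_toy_trace(pos, team=[0] * 11 + [1] * 11)
        occupancy = an.role_box_occupancy(trace, (formation_a, formation_b))
        assert np.allclose(occupancy["mean_dist"], 0.0)
        assert np.allclose(occupancy["inside_fraction"], 1.0)

    def test_player_always_outside(self, formation_a, formation_b):
        pos = np.tile([54.0, -29.0], (6, 22, 1))  # far corner, outside most boxes
        trace = make_toy_trace(pos)
        occupancy = an.role_box_occupancy(trace, (formation_a, formation_b))
        assert occupancy.loc[1, "inside_fraction"] == 0.0  # the A goalkeeper box

    def test_hand_computed_mean_distance(self, formation_a, formation_b):
        centre = formation_a.role_boxes[0].centre
        pos = np.tile([0.0, 0.0], (2, 22, 1))
        pos[:, 0, :] = [centre + (3.0, 4.0), centre + (3.0, 4.0)]
        trace = make_toy_trace(pos)
        occupancy = an.role_box_occupancy(trace, (formation_a, formation_b))
        assert occupancy.loc[1, "mean_dist"] == pytest.approx(5.0)


class TestStepLengths:
    def test_motor_steps_respect_the_cap(self, c1_trace):
        assert an.step_lengths(c1_trace).max() <= 1.0 + 1e-9

    def test_reset_transitions_are_excluded(self, c1_trace):
        with_resets = an.step_lengths(c1_trace, exclude_resets=False)
        goals = [e for e in c1_trace.events if e.kind == "goal"]
        if goals:
            assert with_resets.max() > 1.0  # the kickoff teleport
        assert an.heading_changes(c1_trace).max() <= 180.0
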