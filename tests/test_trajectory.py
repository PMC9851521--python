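import numpy as np
import pytest
from hypothesis import given, strategies as st

from infonav.maze import DefaultPolicy, MazeError, Policy
from infonav.trajectory import (
    ContinuousTrajectory,
    DiscreteTrajectory,
    discretize,
    empirical_control_information,
    has_backtracking,
    infer_empirical_policy,
    initiation_time,
    load_cohort,
    path_reward,
    read_trajectories_csv,
    write_trajectories_csv,
)
from infonav.synthetic import bundled_maze_fixture, simulate_agent, render_continuous, CohortSpec
from infonav.maze import build_mdp

from conftest import make_line


def traj_from_points(points, trial_id="t1"):
    frames = np.array(
        [[i * 0.1, x, y, th] for i, (x, y, th) in enumerate(points)]
    )
    return ContinuousTrajectory(trial_id, frames)


class TestContinuousTrajectory:
    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            ContinuousTrajectory("t", np.array([[0.0, 0, 0, 0]]))

    def test_requires_increasing_timestamps(self):
        with pytest.raises(ValueError, match="increasing"):
            ContinuousTrajectory(
                "t", np.array([[0.0, 0, 0, 0], [0.0, 1, 0, 0]])
            )


class TestDiscretize:
    def test_exact_node_frames_on_line(self, line5):
        traj = traj_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        dt = discretize(traj, line5)
        assert dt.states == [0, 1, 2]
        assert dt.actions == ["E", "E"]

    def test_jitter_below_half_spacing_is_absorbed(self, line5):
        traj = traj_from_points([(0.3, 0.2, 0), (-0.2, -0.3, 0)])
        dt = discretize(traj, line5)
        assert dt.states == [0]
        assert dt.actions == []

    def test_strict_mode_rejects_jumps(self, line5):
        traj = traj_from_points([(0, 0, 0), (2, 0, 0)])
        with pytest.raises(MazeError, match="non-adjacent"):
            discretize(traj, line5, mode="strict")

    def test_lenient_mode_bridges_unique_shortest_path(self, line5):
        traj = traj_from_points([(0, 0, 0), (2, 0, 0), (4, 0, 0)])
        dt = discretize(traj, line5, mode="lenient")
        assert dt.states == [0, 1, 2, 3, 4]

    def test_lenient_mode_rejects_ambiguous_bridge(self):
        from conftest import make_cycle4

        g = make_cycle4()
        traj = traj_from_points([(0, 0, 0), (1, 1, 0)])  # two 2-step bridges
        with pytest.raises(MazeError, match="ambiguous"):
            discretize(traj, g, mode="lenient")

    def test_out_of_bounds_frame_rejected(self, line5):
        traj = traj_from_points([(0, 0, 0), (9, 0, 0)])
        with pytest.raises(MazeError, match="outside"):
            discretize(traj, line5)

    def test_round_trip_with_renderer(self, fixture_maze):
        graph, default = fixture_maze
        mdp = build_mdp(graph, graph.landmark_ids[4])
        dt = simulate_agent(mdp, default, 1.0, graph.landmark_ids[0], seed=3)
        res = render_continuous(dt, None, CohortSpec(), seed=3, graph=graph, jitter=0.0)
        assert discretize(res.trajectory, graph) == dt


class TestEmpiricalPolicy:
    def test_single_visits_give_deterministic_estimate(self):
        dt = DiscreteTrajectory([0, 1, 2], ["E", "E"])
        ep = infer_empirical_policy(dt)
        assert ep.dist(0) == {"E": 1.0}
        assert ep.dist(1) == {"E": 1.0}

    def test_repeat_visit_splits_mass(self):
        # state 1 visited twice, once heading N and once E
        dt = DiscreteTrajectory([1, 5, 1, 2], ["N", "S", "E"])
        ep = infer_empirical_policy(dt)
        assert ep.dist(1) == {"N": 0.5, "E": 0.5}

    def test_empty_trajectory_gives_empty_policy(self):
        dt = DiscreteTrajectory([3], [])
        ep = infer_empirical_policy(dt)
        assert ep.counts == {}

    def test_joint_normalises_over_all_pairs(self):
        dt = DiscreteTrajectory([0, 1, 2], ["E", "E"])
        ep = infer_empirical_policy(dt)
        assert sum(ep.joint.values()) == pytest.approx(1.0)


class TestEmpiricalControlInformation:
    def test_route_follower_pays_only_smoothing(self, fixture_maze):
        graph, default = fixture_maze
        route = default.route
        states = route[:11]
        actions = [default.route_action[s] for s in states[:-1]]
        dt = DiscreteTrajectory(states, actions)
        ep = infer_empirical_policy(dt)
        ihat = empirical_control_information(ep, dt, default)
        assert ihat == pytest.approx(10 * np.log(1 / 0.95), abs=1e-12)

    def test_deviation_at_k_uniform_four_action_nodes(self):
        from infonav.synthetic import generate_maze

        g = generate_maze(5, 6, wall_density=0.0)
        bottom = sorted(
            (s for s in g.node_ids if g.coords(s)[1] == 0),
            key=lambda s: g.coords(s)[0],
        )
        default = DefaultPolicy(g, bottom, epsilon=0.0)
        # walk south along x=1 through 3 interior 4-action nodes, then east
        col = {y: next(s for s in g.node_ids if g.coords(s) == (1, y)) for y in range(4)}
        states = [col[3], col[2], col[1], col[0], bottom[2], bottom[3]]
        actions = ["S", "S", "S", "E", "E"]
        dt = DiscreteTrajectory(states, actions)
        ep = infer_empirical_policy(dt)
        ihat = empirical_control_information(ep, dt, default)
        assert ihat == pytest.approx(3 * np.log(4), abs=1e-12)

    def test_reverse_route_matches_per_step_sum(self, y_maze):
        graph, default, start, goal = y_maze
        # travel the trained loop backwards from goal-side to start-side
        states = [2, 7, 6, 5, 4, 3, 0]
        actions = [
            graph.direction_between(u, v) for u, v in zip(states[:-1], states[1:])
        ]
        dt = DiscreteTrajectory(states, actions)
        ep = infer_empirical_policy(dt)
        ihat = empirical_control_information(ep, dt, default)
        oracle = -sum(
            np.log(default.prob(s, a)) for s, a in zip(states[:-1], actions)
        )
        assert ihat == pytest.approx(oracle, abs=1e-12)

    def test_per_visit_dominates_per_state(self, fixture_maze):
        graph, default = fixture_maze
        mdp = build_mdp(graph, graph.landmark_ids[6])
        rng = np.random.default_rng(5)
        for k in range(10):
            dt = simulate_agent(
                mdp, default, float(rng.uniform(0, 1)), graph.landmark_ids[1], seed=k
            )
            ep = infer_empirical_policy(dt)
            pv = empirical_control_information(ep, dt, default, "per_visit")
            ps = empirical_control_information(ep, dt, default, "per_state")
            assert pv >= ps - 1e-12
            if not has_backtracking(dt):
                assert pv == pytest.approx(ps, abs=1e-12)

    def test_support_violation_with_unsmoothed_default(self, y_maze):
        graph, _, start, goal = y_maze
        default = DefaultPolicy(graph, [0, 3, 4, 5, 6, 7, 2], epsilon=0.0)
        dt = DiscreteTrajectory([0, 1, 2], ["E", "E"])
        ep = infer_empirical_policy(dt)
        with pytest.raises(MazeError, match="infinite control cost"):
            empirical_control_information(ep, dt, default)


class TestPathScalars:
    def test_path_reward_counts_steps(self):
        assert path_reward(DiscreteTrajectory([0, 1, 2, 3, 4], ["E"] * 4)) == -4.0
        assert path_reward(DiscreteTrajectory([7], [])) == 0.0

    def test_backtracking_detection(self):
        assert not has_backtracking(DiscreteTrajectory([0, 1, 2], ["E", "E"]))
        assert has_backtracking(DiscreteTrajectory([0, 1, 0], ["E", "W"]))
        assert has_backtracking(
            DiscreteTrajectory([0, 1, 2, 3, 0], ["E", "N", "W", "S"])
        )

    def test_initiation_time_stationary_then_moving(self):
        frames = np.array(
            [[0.0, 0, 0, 0], [1.0, 0, 0, 0], [2.0, 0, 0, 0], [2.5, 1, 0, 0]]
        )
        traj = ContinuousTrajectory("t", frames)
        assert initiation_time(traj, 0.5) == pytest.approx(2.5)

    def test_initiation_time_immediate_motion(self):
        frames = np.array([[0.0, 0, 0, 0], [0.1, 1, 0, 0], [0.2, 2, 0, 0]])
        assert initiation_time(ContinuousTrajectory("t", frames), 0.5) == pytest.approx(0.1)

    def test_initiation_time_never_moving_returns_duration(self):
        frames = np.array([[0.0, 0, 0, 0], [3.0, 0.1, 0, 0]])
        assert initiation_time(ContinuousTrajectory("t", frames), 0.5) == pytest.approx(3.0)


class TestCsvIO:
    def test_trajectory_csv_round_trip(self, tmp_path):
        t1 = traj_from_points([(0, 0, 10), (1, 0, 20)], "a")
        t2 = traj_from_points([(5, 5, 0), (5, 6, 90), (5, 7, 90)], "b")
        p = tmp_path / "traj.csv"
        write_trajectories_csv([t1, t2], p)
        back = read_trajectories_csv(p)
        assert set(back) == {"a", "b"}
        np.testing.assert_allclose(back["a"].frames, t1.frames)
        np.testing.assert_allclose(back["b"].frames, t2.frames)

    def test_load_cohort_applies_duration_cutoff(self, tmp_path):
        import pandas as pd

        short = traj_from_points([(0, 0, 0), (1, 0, 0)], "short")
        frames = np.array([[0.0, 0, 0, 0], [45.0, 1, 0, 0]])
        long = ContinuousTrajectory("long", frames)
        write_trajectories_csv([short, long], tmp_path / "traj.csv")
        pd.DataFrame(
            {
                "trial_id": ["short", "long"],
                "participant_id": ["p1", "p1"],
                "instruction": ["GTG", "GTG"],
                "gender": ["F", "F"],
                "start_landmark": [0, 0],
                "goal_landmark": [4, 4],
            }
        ).to_csv(tmp_path / "trials.csv", index=False)
        trials, trajs, excluded = load_cohort(
            tmp_path / "traj.csv", tmp_path / "trials.csv", max_duration=40.0
        )
        assert excluded == ["long"]
        assert list(trials["trial_id"]) == ["short"]
        assert set(trajs) == {"short"}
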