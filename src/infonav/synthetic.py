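"""Synthetic mazes, agents and cohorts.

Everything the analysis consumes can be generated here: the bundled
66-node maze with its peripheral training route, random grid mazes,
bounded-rational agents sampling from the optimal Boltzmann policy at a
given beta, a continuous renderer that turns discrete paths into
frame-sampled (t, x, y, heading) traces with planted pause-and-sweep
blocks, and a two-group cohort generator with planted effects (higher beta
in the shortcut group, reward-gap modulation of beta in the goal group and
a logistic RGI -> pause link) for end-to-end parameter-recovery tests.

Renderer conventions: one distance unit = one grid spacing; headings in
degrees (E=0, N=90); frames at a uniform rate.  Outside planted sweep
blocks the heading turns toward the direction of travel at no more than
the angular VTE threshold per frame, so that on a noiseless render the
detected VTE frames are exactly the planted ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Collection, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from infonav.maze import (
    ACTIONS,
    DefaultPolicy,
    MazeError,
    MazeGraph,
    MazeMDP,
    Node,
    Policy,
    build_mdp,
    policy_value_vector,
)
from infonav.inforl import FreeEnergySolution, solve_free_energy
from infonav.trajectory import ContinuousTrajectory, DiscreteTrajectory
from infonav.rgi import RGIConfig, RGIMap, compute_rgi

HEADING = {"E": 0.0, "N": 90.0, "W": 180.0, "S": 270.0}


# ---------------------------------------------------------------------------
# The bundled 66-node maze


def _fixture_layout():
    """Node coordinates, landmarks and training route of the bundled maze.

    The map is a rectangular peripheral ring (the training route) with two
    internal corridors crossing the middle (the shortcuts), one internal
    stub entered from the west wall and one entered from the top wall (the
    dead ends).  It has 66 nodes, 12 perimeter landmarks and 6 nodes of
    degree >= 3.
    """
    W, H = 14, 8  # x in 0..14, y in 0..8
    coords: list[tuple[int, int]] = []
    for x in range(W + 1):
        for y in (0, H):
            coords.append((x, y))
    for y in range(1, H):
        for x in (0, W):
            coords.append((x, y))
    for x in (5, 10):  # internal corridors
        for y in range(1, H):
            coords.append((x, y))
    coords += [(1, 4), (2, 4), (3, 4), (4, 4)]  # west stub (dead end at (4,4))
    coords += [(7, 7), (7, 6), (7, 5), (7, 4)]  # top stub (dead end at (7,4))
    coords = sorted(set(coords), key=lambda c: (c[1], c[0]))
    landmarks = {
        (0, 0): "A",
        (3, 0): "B",
        (7, 0): "C",
        (11, 0): "D",
        (14, 0): "E",
        (14, 4): "F",
        (14, 8): "G",
        (11, 8): "H",
        (3, 8): "I",
        (0, 8): "J",
        (0, 6): "K",
        (0, 2): "L",
    }
    edges_xy: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for x in range(W):  # top and bottom walls
        edges_xy.append(((x, 0), (x + 1, 0)))
        edges_xy.append(((x, H), (x + 1, H)))
    for y in range(H):  # side walls
        edges_xy.append(((0, y), (0, y + 1)))
        edges_xy.append(((W, y), (W, y + 1)))
    for x in (5, 10):  # corridors attach to both walls
        for y in range(H):
            edges_xy.append(((x, y), (x, y + 1)))
    for x in range(4):  # west stub
        edges_xy.append(((x, 4), (x + 1, 4)))
    for y in range(4, 8):  # top stub
        edges_xy.append(((7, y), (7, y + 1)))
    # clockwise peripheral training route, closed
    route_xy = (
        [(x, 0) for x in range(W + 1)]
        + [(W, y) for y in range(1, H + 1)]
        + [(x, H) for x in range(W - 1, -1, -1)]
        + [(0, y) for y in range(H - 1, -1, -1)]
    )
    return coords, landmarks, edges_xy, route_xy


def build_fixture_graph() -> MazeGraph:
    """Construct the bundled maze programmatically (used to write the JSON)."""
    coords, landmarks, edges_xy, route_xy = _fixture_layout()
    index = {c: i for i, c in enumerate(coords)}
    nodes = [
        Node(i, x, y, (x, y) in landmarks, landmarks.get((x, y), ""))
        for (x, y), i in sorted(index.items(), key=lambda kv: kv[1])
    ]
    edges = []
    for (a, b) in edges_xy:
        dx, dy = b[0] - a[0], b[1] - a[1]
        d = {(0, 1): "N", (0, -1): "S", (1, 0): "E", (-1, 0): "W"}[(dx, dy)]
        edges.append((index[a], index[b], d))
    route = [index[c] for c in route_xy]
    return MazeGraph(nodes, edges, metadata={"default_route": route})


def bundled_maze_fixture(epsilon: float = 0.05) -> tuple[MazeGraph, DefaultPolicy]:
    """The bundled 66-node maze and its smoothed training-route policy."""
    with resources.files("infonav.data").joinpath("maze66.json").open() as fh:
        graph = MazeGraph.from_json_dict(json.load(fh))
    route = list(graph.metadata["default_route"])
    return graph, DefaultPolicy(graph, route, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Random grid mazes


def generate_maze(
    width: int,
    height: int,
    wall_density: float = 0.3,
    n_landmarks: int = 0,
    seed: int | None = None,
) -> MazeGraph:
    """Connected 4-neighbour grid maze with seeded wall carving.

    Starts from the full ``width x height`` grid and removes up to
    ``wall_density`` of the edges in a random order, skipping removals
    that would disconnect the graph.  Landmarks are spread along the
    periphery (habitual routes live on the periphery; shortcuts cross the
    middle).
    """
    if width < 3 or height < 3:
        raise MazeError("grid must be at least 3x3")
    if not (0 <= wall_density < 1):
        raise MazeError("wall density must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    index = {(x, y): y * width + x for x in range(width) for y in range(height)}
    g = nx.Graph()
    g.add_nodes_from(index.values())
    pairs = []
    for (x, y), i in index.items():
        if x + 1 < width:
            pairs.append(((x, y), (x + 1, y)))
        if y + 1 < height:
            pairs.append(((x, y), (x, y + 1)))
    g.add_edges_from((index[a], index[b]) for a, b in pairs)
    order = rng.permutation(len(pairs))
    to_remove = int(round(wall_density * len(pairs)))
    removed = 0
    for k in order:
        if removed >= to_remove:
            break
        a, b = pairs[k]
        g.remove_edge(index[a], index[b])
        if nx.is_connected(g):
            removed += 1
        else:
            g.add_edge(index[a], index[b])
    # periphery nodes in boundary order, for landmark placement
    boundary = [
        (x, y)
        for (x, y) in index
        if x in (0, width - 1) or y in (0, height - 1)
    ]
    boundary.sort(key=lambda c: np.arctan2(c[1] - (height - 1) / 2, c[0] - (width - 1) / 2))
    landmark_set = set()
    if n_landmarks:
        picks = np.linspace(0, len(boundary), n_landmarks, endpoint=False).astype(int)
        landmark_set = {boundary[p] for p in picks}
    nodes = [
        Node(i, x, y, (x, y) in landmark_set, "")
        for (x, y), i in sorted(index.items(), key=lambda kv: kv[1])
    ]
    edges = []
    for u, v in g.edges:
        cu = next(c for c, i in index.items() if i == u)
        cv = next(c for c, i in index.items() if i == v)
        d = {(0, 1): "N", (0, -1): "S", (1, 0): "E", (-1, 0): "W"}[
            (cv[0] - cu[0], cv[1] - cu[1])
        ]
        edges.append((u, v, d))
    return MazeGraph(nodes, edges, metadata={"seed": seed, "wall_density": wall_density})


# ---------------------------------------------------------------------------
# Agents


def simulate_agent(
    mdp: MazeMDP,
    default: DefaultPolicy | Policy,
    beta: float,
    start: int,
    seed: int | None = None,
    solution: FreeEnergySolution | None = None,
    step_cap: int | None = None,
    action_noise: float = 0.0,
) -> DiscreteTrajectory:
    """Sample a trajectory from the optimal Boltzmann policy at ``beta``.

    Sampling stops at the goal or at ``step_cap`` (default: 10x the
    shortest-path length); a capped trajectory is flagged incomplete.
    With probability ``action_noise`` a step is replaced by a uniformly
    random available action.
    """
    rng = np.random.default_rng(seed)
    if solution is None:
        solution = solve_free_energy(mdp, default, beta)
    if step_cap is None:
        d = nx.shortest_path_length(mdp.graph.to_networkx(), start, mdp.goal)
        step_cap = max(10, 10 * int(d))
    policy = solution.policy
    states = [start]
    actions: list[str] = []
    s = start
    while s != mdp.goal and len(actions) < step_cap:
        acts = mdp.actions(s)
        if action_noise > 0 and rng.random() < action_noise:
            a = acts[rng.integers(len(acts))]
        else:
            probs = np.array([policy.prob(s, a) for a in acts])
            a = acts[rng.choice(len(acts), p=probs / probs.sum())]
        s = mdp.successor(s, a)
        actions.append(a)
        states.append(s)
    return DiscreteTrajectory(states, actions, complete=(s == mdp.goal))


# ---------------------------------------------------------------------------
# Continuous rendering


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Two instruction groups navigate the bundled maze: "Go To Goal" (GTG)
    agents draw ``beta = gtg_beta0 + gtg_gap_coef * reward_gap`` (resource
    investment scales with what a shortcut could earn) while "Take
    Shortcut" (TS) agents draw a high, gap-independent beta.  At each
    interior node of a rendered path a pause-and-sweep block is planted
    with probability ``logistic(vte_intercept + vte_slope * RGI)``.
    """

    participants_per_group: int = 30
    trials_per_participant: int = 40
    gtg_beta0: float = 0.3
    gtg_gap_coef: float = 0.04
    ts_beta_mean: float = 5.0
    ts_beta_sd: float = 1.0
    ts_beta_min: float = 3.0
    action_noise: float = 0.0
    vte_intercept: float = -3.0
    vte_slope: float = 2.5
    frame_rate: float = 10.0
    speed: float = 2.5
    jitter: float = 0.08
    turn_rate: float = 10.0
    sweep_step: float = 45.0
    sweep_frames_choices: tuple[int, ...] = (8, 10, 12, 14, 16)
    initiation_mean: float = 1.95
    initiation_sd: float = 0.5
    initiation_min: float = 0.2
    duration_cutoff: float = 40.0
    epsilon: float = 0.05
    rgi_beta: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participants_per_group <= 0 or self.trials_per_participant <= 0:
            raise ValueError("cohort counts must be positive")
        if self.duration_cutoff <= 0:
            raise ValueError("duration cutoff must be positive")


@dataclass
class RenderResult:
    trajectory: ContinuousTrajectory
    planted_vte_frames: int
    pause_nodes: list[int]
    planted_initiation: float


def _turn_toward(h: float, target: float, max_step: float) -> float:
    delta = (target - h + 180.0) % 360.0 - 180.0
    if abs(delta) <= max_step:
        return target % 360.0
    return (h + np.sign(delta) * max_step) % 360.0


def render_continuous(
    dt: DiscreteTrajectory,
    rgi_values: Mapping[int, float] | RGIMap | None,
    spec: CohortSpec,
    seed: int | None = None,
    graph: MazeGraph | None = None,
    coords: Mapping[int, tuple[float, float]] | None = None,
    jitter: float | None = None,
    pause_at: Collection[int] | None = None,
    trial_id: str = "trial",
) -> RenderResult:
    """Render a discrete path as a frame-sampled continuous trajectory.

    The agent waits a planted initiation period at the start, then moves
    at constant speed along the edges, heading turning toward the travel
    direction at at most ``spec.turn_rate`` degrees per frame.  On arrival
    at an interior node a pause-and-sweep block (zero speed, alternating
    +/- ``sweep_step`` heading jumps, an even number of frames) is planted
    with the logistic RGI link — or deterministically at the nodes of
    ``pause_at`` when given.  Positional jitter stays below half the grid
    spacing, so a noiseless (or default-jitter) render discretizes back to
    the original path.
    """
    if graph is not None and coords is None:
        coords = {s: graph.coords(s) for s in dt.states}
    if coords is None:
        raise ValueError("need a graph or a coords mapping")
    rgi = rgi_values.values if isinstance(rgi_values, RGIMap) else (rgi_values or {})
    rng = np.random.default_rng(seed)
    jit = spec.jitter if jitter is None else jitter
    fpe = max(2, int(round(spec.frame_rate / spec.speed)))

    xs: list[float] = []
    ys: list[float] = []
    hs: list[float] = []
    flagged = 0
    pause_nodes: list[int] = []

    start = dt.states[0]
    x0, y0 = coords[start]
    if dt.actions:
        h = HEADING[dt.actions[0]]
    else:
        h = 0.0
    initiation = max(
        spec.initiation_min,
        float(rng.normal(spec.initiation_mean, spec.initiation_sd)),
    )
    n0 = max(1, int(round(initiation * spec.frame_rate)))
    for _ in range(n0):
        xs.append(x0)
        ys.append(y0)
        hs.append(h)

    for k, (u, v, a) in enumerate(zip(dt.states[:-1], dt.states[1:], dt.actions)):
        ux, uy = coords[u]
        vx, vy = coords[v]
        target = HEADING[a]
        for j in range(1, fpe + 1):
            h = _turn_toward(h, target, spec.turn_rate)
            xs.append(ux + (vx - ux) * j / fpe)
            ys.append(uy + (vy - uy) * j / fpe)
            hs.append(h)
        if v != dt.states[-1]:
            if pause_at is not None:
                pause = v in set(pause_at)
            else:
                logit = spec.vte_intercept + spec.vte_slope * rgi.get(v, 0.0)
                pause = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
            if pause:
                K = int(rng.choice(spec.sweep_frames_choices))
                K += K % 2  # even: the sweep returns to the travel heading
                for j in range(1, K + 1):
                    xs.append(vx)
                    ys.append(vy)
                    hs.append((h + spec.sweep_step) % 360.0 if j % 2 else h)
                flagged += K
                pause_nodes.append(v)

    n = len(xs)
    t = np.arange(n) / spec.frame_rate
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if jit > 0:
        xs = xs + rng.uniform(-jit, jit, n)
        ys = ys + rng.uniform(-jit, jit, n)
    frames = np.column_stack([t, xs, ys, np.asarray(hs)])
    traj = ContinuousTrajectory(
        trial_id,
        frames,
        start_landmark=dt.states[0],
        goal_landmark=dt.states[-1],
    )
    return RenderResult(
        trajectory=traj,
        planted_vte_frames=flagged,
        pause_nodes=pause_nodes,
        planted_initiation=initiation,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortData:
    """A generated cohort with its ground truth."""

    spec: CohortSpec
    graph: MazeGraph
    default: DefaultPolicy
    rgi_map: RGIMap
    trials: pd.DataFrame
    trajectories: dict[str, ContinuousTrajectory]
    ground_truth: pd.DataFrame
    excluded: list[str]


def generate_cohort(
    spec: CohortSpec,
    graph: MazeGraph | None = None,
    default: DefaultPolicy | None = None,
) -> CohortData:
    """Generate the two-group cohort on the bundled (or a given) maze.

    Every trial draws a distinct start/goal landmark pair, a beta from the
    instruction rule, samples the optimal Boltzmann agent, renders it
    continuously and applies the trial-duration cutoff.  All randomness
    descends hierarchically from ``spec.seed``; ground truth (true beta,
    planted VTE frames, planted initiation, exclusions) is returned for
    recovery tests.
    """
    if graph is None or default is None:
        graph, default = bundled_maze_fixture(epsilon=spec.epsilon)
    landmarks = graph.landmark_ids
    rgi_map = compute_rgi(graph, RGIConfig(goals=landmarks, beta=spec.rgi_beta))

    mdps: dict[int, MazeMDP] = {g: build_mdp(graph, g) for g in landmarks}
    gx = graph.to_networkx()
    v_rho: dict[int, np.ndarray] = {
        g: policy_value_vector(mdps[g], default) for g in landmarks
    }
    d_sp: dict[int, dict[int, int]] = {
        g: dict(nx.single_source_shortest_path_length(gx, g)) for g in landmarks
    }
    solutions: dict[tuple[int, float], FreeEnergySolution] = {}

    master = np.random.SeedSequence(spec.seed)
    trial_rows = []
    gt_rows = []
    trajectories: dict[str, ContinuousTrajectory] = {}
    excluded: list[str] = []

    groups = [("GTG", i) for i in range(spec.participants_per_group)] + [
        ("TS", i) for i in range(spec.participants_per_group)
    ]
    part_seeds = master.spawn(len(groups))
    for (instruction, pi), pseq in zip(groups, part_seeds):
        participant = f"{instruction}{pi + 1:02d}"
        prng = np.random.default_rng(pseq)
        gender = "M" if prng.random() < 0.5 else "F"
        trial_seeds = pseq.spawn(spec.trials_per_participant)
        for ti, tseq in enumerate(trial_seeds):
            trng = np.random.default_rng(tseq)
            start, goal = map(int, trng.choice(landmarks, size=2, replace=False))
            gap = float(-d_sp[goal][start] - v_rho[goal][mdps[goal].index(start)])
            if instruction == "GTG":
                beta = spec.gtg_beta0 + spec.gtg_gap_coef * gap
            else:
                beta = max(
                    spec.ts_beta_min,
                    float(trng.normal(spec.ts_beta_mean, spec.ts_beta_sd)),
                )
            key = (goal, round(beta, 6))
            if key not in solutions:
                solutions[key] = solve_free_energy(mdps[goal], default, beta)
            dt = simulate_agent(
                mdps[goal],
                default,
                beta,
                start,
                seed=tseq.spawn(1)[0],
                solution=solutions[key],
                action_noise=spec.action_noise,
            )
            trial_id = f"{participant}_t{ti + 1:02d}"
            render = render_continuous(
                dt,
                rgi_map,
                spec,
                seed=tseq.spawn(1)[0],
                graph=graph,
                trial_id=trial_id,
            )
            traj = render.trajectory
            over_cutoff = traj.duration > spec.duration_cutoff
            gt_rows.append(
                {
                    "trial_id": trial_id,
                    "participant_id": participant,
                    "instruction": instruction,
                    "beta_true": beta,
                    "reward_gap": gap,
                    "planted_vte_frames": render.planted_vte_frames,
                    "planted_pauses": len(render.pause_nodes),
                    "planted_initiation_s": render.planted_initiation,
                    "path_steps": len(dt),
                    "complete": dt.complete,
                    "excluded": over_cutoff,
                }
            )
            if over_cutoff:
                excluded.append(trial_id)
                continue
            trial_rows.append(
                {
                    "trial_id": trial_id,
                    "participant_id": participant,
                    "instruction": instruction,
                    "gender": gender,
                    "start_landmark": start,
                    "goal_landmark": goal,
                }
            )
            trajectories[trial_id] = traj
    return CohortData(
        spec=spec,
        graph=graph,
        default=default,
        rgi_map=rgi_map,
        trials=pd.DataFrame(trial_rows),
        trajectories=trajectories,
        ground_truth=pd.DataFrame(gt_rows),
        excluded=excluded,
    )


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write the trials table, trajectories and ground truth as CSV."""
    from pathlib import Path

    from infonav.trajectory import write_trajectories_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.trials.to_csv(out / "trials.csv", index=False)
    write_trajectories_csv(cohort.trajectories.values(), out / "trajectories.csv")
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
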