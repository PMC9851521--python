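"""Continuous trajectories, graph snapping and empirical control information.

Recorded trials arrive as frame sequences ``(t, x, y, heading)``.  They are
snapped to the maze graph by nearest-node assignment, compressed into a
state-action sequence, and scored: the per-trial policy estimate comes from
the state-action co-occurrence matrix, and the empirical control information
sums the per-state KL divergences from the default policy along the path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

from infonav.maze import DefaultPolicy, MazeError, MazeGraph, Policy
from infonav.inforl import per_state_control_info


@dataclass
class ContinuousTrajectory:
    """Raw frames of a single trial.

    ``frames`` is an ``(n, 4)`` array with columns ``t`` (seconds), ``x``,
    ``y`` (grid units) and ``theta`` (heading, degrees).
    """

    trial_id: str
    frames: np.ndarray
    start_landmark: int | None = None
    goal_landmark: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 4:
            raise ValueError("frames must be an (n, 4) array of (t, x, y, theta)")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if np.any(np.diff(self.frames[:, 0]) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.frames[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.frames[:, 1:3]

    @property
    def theta(self) -> np.ndarray:
        return self.frames[:, 3]

    @property
    def duration(self) -> float:
        return float(self.frames[-1, 0] - self.frames[0, 0])


@dataclass
class DiscreteTrajectory:
    """Snapped state-action sequence of one trial."""

    states: list[int]
    actions: list[str]
    visit_times: list[float] | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        if len(self.states) != len(self.actions) + 1:
            raise ValueError("need exactly one more state than actions")

    @property
    def terminal(self) -> int:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.actions)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DiscreteTrajectory)
            and self.states == other.states
            and self.actions == other.actions
        )


@dataclass
class EmpiricalPolicy:
    """Co-occurrence counts and the per-state conditional policy estimate."""

    counts: dict[int, dict[str, int]]

    @property
    def joint(self) -> dict[tuple[int, str], float]:
        total = sum(c for d in self.counts.values() for c in d.values())
        if total == 0:
            return {}
        return {
            (s, a): c / total for s, d in self.counts.items() for a, c in d.items()
        }

    def dist(self, s: int) -> dict[str, float]:
        d = self.counts[s]
        total = sum(d.values())
        return {a: c / total for a, c in d.items()}

    def states(self) -> list[int]:
        return sorted(self.counts)


def assign_frames(traj: ContinuousTrajectory, graph: MazeGraph, bounds_tol: float = 0.75) -> np.ndarray:
    """Nearest maze node for every frame (ties broken by lowest node id)."""
    coords = graph.coord_array()
    ids = np.array(graph.node_ids)
    xy = traj.xy
    lo = coords.min(axis=0) - bounds_tol
    hi = coords.max(axis=0) + bounds_tol
    if np.any(xy < lo) or np.any(xy > hi):
        raise MazeError("frame outside maze bounds")
    d2 = ((xy[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return ids[np.argmin(d2, axis=1)]  # argmin keeps the lowest id on ties


def discretize(
    traj: ContinuousTrajectory,
    graph: MazeGraph,
    mode: Literal["strict", "lenient"] = "strict",
    goal: int | None = None,
) -> DiscreteTrajectory:
    """Snap a continuous trajectory to a graph state-action sequence.

    Consecutive frames snapping to the same node are compressed.  In
    ``strict`` mode a jump between non-adjacent nodes is an error; in
    ``lenient`` mode it is bridged by the unique shortest path between them
    (ambiguity is an error).  The visit time of a state is the timestamp of
    the first frame assigned to it.
    """
    nodes = assign_frames(traj, graph)
    t = traj.t
    states: list[int] = [int(nodes[0])]
    times: list[float] = [float(t[0])]
    for k in range(1, len(nodes)):
        if nodes[k] != states[-1]:
            states.append(int(nodes[k]))
            times.append(float(t[k]))
    # bridge or reject non-adjacent jumps
    g = None
    full_states: list[int] = [states[0]]
    full_times: list[float] = [times[0]]
    for s, ts in zip(states[1:], times[1:]):
        prev = full_states[-1]
        if graph.direction_between(prev, s) is not None:
            full_states.append(s)
            full_times.append(ts)
            continue
        if mode == "strict":
            raise MazeError(f"non-adjacent jump {prev} -> {s}")
        if g is None:
            g = graph.to_networkx()
        paths = list(nx.all_shortest_paths(g, prev, s))
        if len(paths) > 1:
            raise MazeError(f"ambiguous bridge {prev} -> {s}")
        for mid in paths[0][1:]:
            full_states.append(int(mid))
            full_times.append(ts)
    actions = [
        graph.direction_between(u, v)
        for u, v in zip(full_states[:-1], full_states[1:])
    ]
    complete = goal is None or full_states[-1] == goal
    return DiscreteTrajectory(full_states, actions, full_times, complete=complete)


def infer_empirical_policy(dt: DiscreteTrajectory) -> EmpiricalPolicy:
    """State-action co-occurrence counts of a single trial, normalised
    per visited state."""
    counts: dict[int, dict[str, int]] = {}
    for s, a in zip(dt.states[:-1], dt.actions):
        counts.setdefault(s, {}).setdefault(a, 0)
        counts[s][a] += 1
    return EmpiricalPolicy(counts)


def empirical_control_information(
    ep: EmpiricalPolicy,
    dt: DiscreteTrajectory,
    default: DefaultPolicy | Policy,
    semantics: Literal["per_visit", "per_state"] = "per_visit",
) -> float:
    """Empirical control information of one trajectory, in nats.

    Sums ``KL(pi_hat(.|s) || rho(.|s))`` over the trajectory's non-terminal
    states: once per time-step (``per_visit``, the accumulation that defines
    the expected control information) or once per unique visited state
    (``per_state``, the literal set-sum reading).
    """
    graph = default.graph
    kl_cache: dict[int, float] = {}

    def kl(s: int) -> float:
        if s not in kl_cache:
            acts = graph.actions(s)
            pi = ep.dist(s)
            kl_cache[s] = per_state_control_info(
                [pi.get(a, 0.0) for a in acts],
                [default.prob(s, a) for a in acts],
            )
        return kl_cache[s]

    if semantics == "per_visit":
        return float(sum(kl(s) for s in dt.states[:-1]))
    if semantics == "per_state":
        return float(sum(kl(s) for s in set(dt.states[:-1])))
    raise ValueError(f"unknown semantics {semantics!r}")


def path_reward(dt: DiscreteTrajectory) -> float:
    """Reward of the realised path: -1 per action taken."""
    return -float(len(dt.actions))


def has_backtracking(dt: DiscreteTrajectory) -> bool:
    """True iff any node occurs at least twice in the state sequence."""
    return len(set(dt.states)) < len(dt.states)


def initiation_time(
    traj: ContinuousTrajectory, displacement_threshold: float = 0.5
) -> float:
    """Seconds until the participant first moves away from the start.

    Returns the time (relative to the first frame) of the first frame whose
    displacement from the start position exceeds the threshold, or the full
    trial duration if that never happens.
    """
    disp = np.hypot(*(traj.xy - traj.xy[0]).T)
    beyond = np.nonzero(disp > displacement_threshold)[0]
    if len(beyond) == 0:
        return traj.duration
    return float(traj.t[beyond[0]] - traj.t[0])


# ---------------------------------------------------------------------------
# CSV readers / writers (trajectory dialect: trial_id, t, x, y, theta_deg;
# trials table: trial_id, participant_id, instruction, gender,
# start_landmark, goal_landmark)

TRAJ_COLUMNS = ["trial_id", "t", "x", "y", "theta_deg"]
TRIAL_COLUMNS = [
    "trial_id",
    "participant_id",
    "instruction",
    "gender",
    "start_landmark",
    "goal_landmark",
]


def write_trajectories_csv(trajectories: Iterable[ContinuousTrajectory], path) -> None:
    rows = []
    for traj in trajectories:
        df = pd.DataFrame(traj.frames, columns=["t", "x", "y", "theta_deg"])
        df.insert(0, "trial_id", traj.trial_id)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path) -> dict[str, ContinuousTrajectory]:
    df = pd.read_csv(path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    out = {}
    for trial_id, grp in df.groupby("trial_id", sort=False):
        out[str(trial_id)] = ContinuousTrajectory(
            str(trial_id), grp[["t", "x", "y", "theta_deg"]].to_numpy()
        )
    return out


def read_trials_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials table missing columns {sorted(missing)}")
    df["trial_id"] = df["trial_id"].astype(str)
    return df


def load_cohort(
    trajectories_csv,
    trials_csv,
    max_duration: float = 40.0,
) -> tuple[pd.DataFrame, dict[str, ContinuousTrajectory], list[str]]:
    """Read a cohort, dropping trials longer than ``max_duration`` seconds.

    Returns the filtered trials table, the matching trajectories and the
    ids of excluded trials.
    """
    trials = read_trials_table(trials_csv)
    trajs = read_trajectories_csv(trajectories_csv)
    excluded = [tid for tid, tr in trajs.items() if tr.duration > max_duration]
    keep = {tid for tid in trajs if tid not in set(excluded)}
    trials = trials[trials["trial_id"].isin(keep)].reset_index(drop=True)
    trajs = {tid: tr for tid, tr in trajs.items() if tid in keep}
    return trials, trajs, excluded
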