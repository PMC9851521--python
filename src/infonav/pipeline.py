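"""Per-trial metrics and group-level analyses.

Composes the maze, frontier, trajectory and VTE machinery into one row of
metrics per trial, then reproduces the group-level analyses: strategy
classification against the optimal frontier, the RGI-VTE correlation with
centrality controls, instruction/gender contrasts on control information
per step, the reward-gap regression, and cross-trial variability
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from infonav.maze import (
    DefaultPolicy,
    MazeError,
    MazeGraph,
    MazeMDP,
    build_mdp,
    policy_value_vector,
)
from infonav.inforl import (
    Frontier,
    TradeoffPoint,
    default_beta_grid,
    distance_from_frontier,
    evaluate_info_value,
    solve_free_energy,
)
from infonav.trajectory import (
    ContinuousTrajectory,
    discretize,
    empirical_control_information,
    has_backtracking,
    infer_empirical_policy,
    initiation_time,
    path_reward,
)
from infonav.vte import VTEConfig, detect_vte_frames, kinematics, vte_rate

DEFAULT_TAU = 0.05


class FrontierCache:
    """Per-goal frontier solves, shared across trials.

    For one goal, the free-energy solution at each beta yields per-state
    (information, value) vectors, so frontiers for every start node of
    that goal cost a single sweep.
    """

    def __init__(
        self,
        graph: MazeGraph,
        default: DefaultPolicy,
        beta_grid=None,
    ) -> None:
        self.graph = graph
        self.default = default
        self.beta_grid = (
            default_beta_grid() if beta_grid is None else np.asarray(beta_grid)
        )
        self._mdps: dict[int, MazeMDP] = {}
        self._tables: dict[int, list] = {}
        self._v_rho: dict[int, np.ndarray] = {}

    def mdp(self, goal: int) -> MazeMDP:
        if goal not in self._mdps:
            self._mdps[goal] = build_mdp(self.graph, goal)
        return self._mdps[goal]

    def _table(self, goal: int):
        if goal not in self._tables:
            mdp = self.mdp(goal)
            from infonav.inforl import control_info_vector

            rows = []
            for beta in self.beta_grid:
                sol = solve_free_energy(mdp, self.default, float(beta))
                I = control_info_vector(mdp, self.default, sol.policy)
                V = policy_value_vector(mdp, sol.policy)
                rows.append((float(beta), I, V))
            self._tables[goal] = rows
        return self._tables[goal]

    def frontier(self, start: int, goal: int) -> Frontier:
        mdp = self.mdp(goal)
        i0 = mdp.index(start)
        points = [
            TradeoffPoint(beta=b, control_info=float(I[i0]), value=float(V[i0]))
            for b, I, V in self._table(goal)
        ]
        return Frontier(
            start=start, goal=goal, points=points, epsilon=self.default.epsilon
        )

    def default_value(self, start: int, goal: int) -> float:
        """V_rho(start) for the given goal, from an exact linear solve."""
        if goal not in self._v_rho:
            self._v_rho[goal] = policy_value_vector(self.mdp(goal), self.default)
        return float(self._v_rho[goal][self.mdp(goal).index(start)])

    def reward_gap(self, start: int, goal: int) -> float:
        """Shortest-route reward minus default-policy reward (>= 0)."""
        import networkx as nx

        d = nx.shortest_path_length(self.graph.to_networkx(), start, goal)
        return float(-d - self.default_value(start, goal))


@dataclass
class TrialMetrics:
    """One scored trial."""

    trial_id: str
    participant_id: str
    instruction: str
    gender: str
    start: int
    goal: int
    path_length: int
    reward: float
    control_info: float
    info_per_step: float
    frontier_distance: float
    strategy: str
    backtracking: bool
    vte_rate: float
    initiation_time: float
    reward_gap: float
    complete: bool


def classify_strategy(
    frontier_distance: float, backtracking: bool, tau: float = DEFAULT_TAU
) -> str:
    """Optimal if within ``tau`` of the frontier; otherwise the
    backtracking flag splits the suboptimal classes."""
    if frontier_distance <= tau:
        return "optimal"
    return "suboptimal_backtracking" if backtracking else "suboptimal_no_backtracking"


def compute_trial_metrics(
    traj: ContinuousTrajectory,
    graph: MazeGraph,
    default: DefaultPolicy,
    frontier_cache: FrontierCache,
    trial_info: Mapping | None = None,
    vte_cfg: VTEConfig | None = None,
    tau: float = DEFAULT_TAU,
    semantics: str = "per_visit",
) -> TrialMetrics:
    """Score one trial: discretize, estimate the policy, and compose the
    information, reward, frontier-distance, VTE and timing metrics.

    A single-trajectory estimate can land marginally above the expected-
    value frontier (the estimate is not a policy expectation); such points
    are treated as on-curve (distance 0).
    """
    info = dict(trial_info or {})
    start = int(info.get("start_landmark", -1))
    goal = int(info.get("goal_landmark", -1))
    dt = discretize(traj, graph, mode="lenient", goal=goal if goal >= 0 else None)
    if start < 0:
        start = dt.states[0]
    if goal < 0:
        goal = dt.terminal
    ep = infer_empirical_policy(dt)
    ihat = (
        empirical_control_information(ep, dt, default, semantics=semantics)
        if len(dt) > 0
        else 0.0
    )
    reward = path_reward(dt)
    steps = len(dt)
    frontier = frontier_cache.frontier(start, goal)
    try:
        dist = distance_from_frontier(frontier, (ihat, reward))
    except MazeError:
        dist = 0.0
    back = has_backtracking(dt)
    cfg = vte_cfg or VTEConfig()
    kin = kinematics(traj, cfg)
    rate = vte_rate(detect_vte_frames(kin, cfg))
    return TrialMetrics(
        trial_id=str(traj.trial_id),
        participant_id=str(info.get("participant_id", "")),
        instruction=str(info.get("instruction", "")),
        gender=str(info.get("gender", "")),
        start=start,
        goal=goal,
        path_length=steps,
        reward=reward,
        control_info=ihat,
        info_per_step=ihat / steps if steps else 0.0,
        frontier_distance=dist,
        strategy=classify_strategy(dist, back, tau),
        backtracking=back,
        vte_rate=rate,
        initiation_time=initiation_time(traj),
        reward_gap=frontier_cache.reward_gap(start, goal),
        complete=dt.complete,
    )


def metrics_table(
    trials: pd.DataFrame,
    trajectories: Mapping[str, ContinuousTrajectory],
    graph: MazeGraph,
    default: DefaultPolicy,
    frontier_cache: FrontierCache | None = None,
    vte_cfg: VTEConfig | None = None,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Score every trial of a cohort into one tidy DataFrame."""
    cache = frontier_cache or FrontierCache(graph, default)
    rows = []
    for rec in trials.to_dict("records"):
        traj = trajectories[str(rec["trial_id"])]
        rows.append(
            asdict(
                compute_trial_metrics(
                    traj, graph, default, cache, trial_info=rec, vte_cfg=vte_cfg, tau=tau
                )
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-level analyses


def rgi_vte_correlation(
    rgi_map: Mapping[int, float],
    per_state_vte: Mapping[int, float],
    exclusions: Iterable[int] = (),
) -> tuple[float, float]:
    """Pearson correlation between per-state RGI and mean VTE rate."""
    values = rgi_map.values if hasattr(rgi_map, "values") and not isinstance(rgi_map, dict) else rgi_map
    excl = set(exclusions)
    common = sorted(
        (set(values) & set(per_state_vte)) - excl
    )
    common = [s for s in common if np.isfinite(values[s])]
    if len(common) < 3:
        raise ValueError("need at least 3 common states")
    x = np.array([values[s] for s in common])
    y = np.array([per_state_vte[s] for s in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_dependent_correlations(
    r_xy: float, r_xz: float, r_yz: float, n: int
) -> tuple[float, float]:
    """Two-sided test for r_xy vs r_xz sharing the common variable x.

    Overlapping dependent correlations, Meng-Rosenthal-Rubin z on the
    Fisher transforms; swapping y and z negates z.
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    z1 = np.arctanh(r_xy)
    z2 = np.arctanh(r_xz)
    rbar2 = (r_xy**2 + r_xz**2) / 2.0
    f = min(1.0, (1.0 - r_yz) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_yz) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    p_value: float
    stderr: float
    ci_low: float
    ci_high: float
    n: int


def reward_gap_regression(
    metrics: pd.DataFrame, mode: str = "per_trial"
) -> dict[str, RegressionFit]:
    """OLS of control information per step on the trial reward gap,
    fit separately per instruction group.

    ``binned`` mode first averages trials sharing a reward gap.
    """
    if mode not in ("per_trial", "binned"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for instruction, grp in metrics.groupby("instruction"):
        if mode == "binned":
            grp = (
                grp.groupby("reward_gap", as_index=False)["info_per_step"].mean()
            )
        x = grp["reward_gap"].to_numpy(dtype=float)
        y = grp["info_per_step"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"degenerate design for group {instruction}")
        fit = stats.linregress(x, y)
        tcrit = stats.t.ppf(0.975, len(x) - 2)
        out[str(instruction)] = RegressionFit(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            p_value=float(fit.pvalue),
            stderr=float(fit.stderr),
            ci_low=float(fit.slope - tcrit * fit.stderr),
            ci_high=float(fit.slope + tcrit * fit.stderr),
            n=len(x),
        )
    return out


def group_comparisons(metrics: pd.DataFrame) -> dict:
    """Instruction and gender contrasts.

    Welch t-tests on per-subject mean control information per step
    (instruction: TS - GTG; gender: M - F), a Levene/Brown-Forsythe test
    on the variance of per-trial control information per step across
    instructions, and a two-sample KS test on per-trial VTE rates.
    """
    subj = (
        metrics.groupby(["participant_id", "instruction", "gender"], as_index=False)[
            "info_per_step"
        ].mean()
    )
    for col in ("instruction", "gender"):
        if subj.groupby(col)["participant_id"].count().min() < 2:
            raise ValueError(f"need at least 2 subjects per {col} group")
    gtg = subj.loc[subj.instruction == "GTG", "info_per_step"]
    ts = subj.loc[subj.instruction == "TS", "info_per_step"]
    t_instr = stats.ttest_ind(ts, gtg, equal_var=False)
    male = subj.loc[subj.gender == "M", "info_per_step"]
    female = subj.loc[subj.gender == "F", "info_per_step"]
    t_gender = stats.ttest_ind(male, female, equal_var=False)
    lev = stats.levene(
        metrics.loc[metrics.instruction == "GTG", "info_per_step"],
        metrics.loc[metrics.instruction == "TS", "info_per_step"],
        center="median",
    )
    ks = stats.ks_2samp(
        metrics.loc[metrics.instruction == "GTG", "vte_rate"],
        metrics.loc[metrics.instruction == "TS", "vte_rate"],
    )
    return {
        "instruction_effect": float(ts.mean() - gtg.mean()),
        "instruction_t": float(t_instr.statistic),
        "instruction_p": float(t_instr.pvalue),
        "gender_effect": float(male.mean() - female.mean()),
        "gender_t": float(t_gender.statistic),
        "gender_p": float(t_gender.pvalue),
        "levene_W": float(lev.statistic),
        "levene_p": float(lev.pvalue),
        "ks_vte_D": float(ks.statistic),
        "ks_vte_p": float(ks.pvalue),
        "n_subjects": int(len(subj)),
    }


def variability_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-participant median, IQR and SD of control information per step
    and frontier distance, sorted by the information median."""
    counts = metrics.groupby("participant_id")["trial_id"].count()
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per participant")

    def iqr(x):
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    rows = []
    for pid, grp in metrics.groupby("participant_id"):
        rows.append(
            {
                "participant_id": pid,
                "instruction": grp["instruction"].iloc[0],
                "info_per_step_median": float(grp["info_per_step"].median()),
                "info_per_step_iqr": iqr(grp["info_per_step"]),
                "info_per_step_sd": float(grp["info_per_step"].std(ddof=1)),
                "frontier_distance_median": float(grp["frontier_distance"].median()),
                "frontier_distance_iqr": iqr(grp["frontier_distance"]),
                "frontier_distance_sd": float(grp["frontier_distance"].std(ddof=1)),
                "n_trials": int(len(grp)),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("info_per_step_median", kind="mergesort")
        .reset_index(drop=True)
    )
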