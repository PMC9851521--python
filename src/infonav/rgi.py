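"""Relevant goal information per maze state.

RGI(s) = I(G; A | s) = H(a|s) - sum_g p(g) H(a|s,g): the number of nats of
goal knowledge that action selection at state ``s`` requires, under the
optimality condition of reaching the goal by a shortest path.  It is
computed by alternating (Blahut-Arimoto style) minimisation over
goal-conditioned policies:

    p(a|s,g)  <-  p(a|s) exp(beta * Q_g(s,a)) / Z(s,g)
    p(a|s)    <-  sum_g p(g) p(a|s,g)

where ``Q_g(s,a) = -1 - d(P(s,a), g)`` is the shortest-path action value.
Each double update decreases the rate-distortion style objective
``I(G;A|s) - beta * E[Q]`` monotonically.  At large beta the conditionals
concentrate on the strictly optimal actions, so RGI approaches its
optimal-behaviour limit; corridors where every goal demands the same action
have RGI 0, and a junction whose k goals demand k distinct actions (with a
uniform prior) approaches ln k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from infonav.maze import MazeError, MazeGraph

LN2 = float(np.log(2.0))


class RGIConvergenceError(RuntimeError):
    def __init__(self, state: int, delta: float):
        super().__init__(
            f"Blahut-Arimoto did not converge at state {state} "
            f"(last objective delta {delta:.3e})"
        )
        self.state = state
        self.delta = delta


@dataclass
class RGIConfig:
    """Configuration of the per-state RGI computation.

    ``beta`` (> 0) sets how sharply goal-conditioned policies concentrate
    on optimal actions; the default 50 is effectively the optimal-behaviour
    limit while keeping the updates numerically smooth.  The goal prior
    defaults to uniform over ``goals``.
    """

    goals: Sequence[int]
    prior: Sequence[float] | None = None
    beta: float = 50.0
    tol: float = 1e-12
    max_iter: int = 10_000
    unit: str = "nats"

    def __post_init__(self) -> None:
        self.goals = list(self.goals)
        if not self.goals:
            raise ValueError("goal set must be non-empty")
        if self.prior is None:
            self.prior = [1.0 / len(self.goals)] * len(self.goals)
        self.prior = list(map(float, self.prior))
        if len(self.prior) != len(self.goals):
            raise ValueError("prior length must match goal set")
        if abs(sum(self.prior) - 1.0) > 1e-9 or min(self.prior) < 0:
            raise ValueError("prior must be a probability vector")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError("beta must be positive and finite")
        if self.unit not in ("nats", "bits"):
            raise ValueError("unit must be 'nats' or 'bits'")


@dataclass
class RGIMap:
    """Per-state RGI values with the underlying marginals and conditionals."""

    values: dict[int, float]
    marginals: dict[int, dict[str, float]]
    conditionals: dict[int, dict[int, dict[str, float]]]
    converged: bool
    unit: str = "nats"
    objective_trace: dict[int, list[float]] = field(default_factory=dict)

    def __getitem__(self, s: int) -> float:
        return self.values[s]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"state_id": sorted(self.values), "rgi": [self.values[s] for s in sorted(self.values)]}
        )


def goal_value(graph: MazeGraph, g: int) -> dict[int, dict[str, float]]:
    """Shortest-path action values Q_g(s, a) = -1 - d(successor, g).

    At the goal state itself Q is 0 for every action (no action needed).
    """
    if g not in graph.nodes:
        raise MazeError(f"goal {g} not in graph")
    dist = nx.single_source_shortest_path_length(graph.to_networkx(), g)
    if len(dist) < len(graph.nodes):
        raise MazeError(f"goal {g} unreachable from some states")
    out: dict[int, dict[str, float]] = {}
    for s in graph.node_ids:
        if s == g:
            out[s] = {a: 0.0 for a in graph.actions(s)}
        else:
            out[s] = {
                a: -1.0 - dist[graph.neighbor(s, a)] for a in graph.actions(s)
            }
    return out


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def compute_rgi(graph: MazeGraph, cfg: RGIConfig) -> RGIMap:
    """Alternating minimisation of I(G;A|s) - beta E[Q], state by state.

    A goal colocated with the evaluated state poses no action requirement:
    it is dropped from the mixture there and the prior renormalised.  A
    state whose renormalised goal set is empty gets ``nan`` (flagged by the
    caller via ``isnan``).
    """
    q_tables = {g: goal_value(graph, g) for g in cfg.goals}
    values: dict[int, float] = {}
    marginals: dict[int, dict[str, float]] = {}
    conditionals: dict[int, dict[int, dict[str, float]]] = {}
    trace: dict[int, list[float]] = {}
    all_converged = True
    for s in graph.node_ids:
        acts = graph.actions(s)
        goals = [g for g in cfg.goals if g != s]
        prior = np.array([p for g, p in zip(cfg.goals, cfg.prior) if g != s])
        if len(goals) == 0 or prior.sum() == 0:
            values[s] = float("nan")
            marginals[s] = {a: 1.0 / len(acts) for a in acts}
            conditionals[s] = {}
            continue
        prior = prior / prior.sum()
        Q = np.array([[q_tables[g][s][a] for a in acts] for g in goals])
        logweights = cfg.beta * Q  # (n_goals, n_actions)
        p_a = np.full(len(acts), 1.0 / len(acts))
        objective_prev = np.inf
        history: list[float] = []
        converged = False
        for _ in range(cfg.max_iter):
            with np.errstate(divide="ignore"):
                logp_a = np.where(p_a > 0, np.log(p_a), -np.inf)
            logc = logp_a[None, :] + logweights
            logc -= logc.max(axis=1, keepdims=True)
            cond = np.exp(logc)
            cond /= cond.sum(axis=1, keepdims=True)
            p_a = prior @ cond
            # rate-distortion objective I(G;A|s) - beta E[Q]
            mi = sum(
                prior[k] * (-_entropy(cond[k]))
                for k in range(len(goals))
            ) + _entropy(p_a)
            eq = float((prior[:, None] * cond * Q).sum())
            objective = mi - cfg.beta * eq
            history.append(objective)
            if abs(objective_prev - objective) < cfg.tol:
                converged = True
                break
            objective_prev = objective
        if not converged:
            raise RGIConvergenceError(s, abs(objective_prev - objective))
        all_converged = all_converged and converged
        rgi = _entropy(p_a) - float(
            sum(prior[k] * _entropy(cond[k]) for k in range(len(goals)))
        )
        rgi = max(rgi, 0.0)
        if cfg.unit == "bits":
            rgi /= LN2
        values[s] = rgi
        marginals[s] = {a: float(p) for a, p in zip(acts, p_a)}
        conditionals[s] = {
            g: {a: float(c) for a, c in zip(acts, cond[k])}
            for k, g in enumerate(goals)
        }
        trace[s] = history
    return RGIMap(
        values=values,
        marginals=marginals,
        conditionals=conditionals,
        converged=all_converged,
        unit=cfg.unit,
        objective_trace=trace,
    )
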