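"""Free-energy Bellman iteration and the reward/control-information frontier.

For a trade-off parameter ``beta >= 0`` the optimal bounded-rational policy
minimises the free energy ``F(s0; beta) = I(s0; pi) - beta * V(s0; pi)``,
where ``I`` is the expected cumulative KL divergence from the default policy
``rho`` and ``V`` the expected reward.  The optimal free energy satisfies a
soft Bellman equation

    F*(s) = -log sum_a rho(a|s) exp(beta * R(s, a) - F*(P(s, a)))

with ``F*(goal) = 0``; the minimising policy is Boltzmann-shaped,
``pi*(a|s) proportional to rho(a|s) exp(beta R - F*(succ))``.  Sweeping beta
from 0 to infinity traces the concave frontier between the default policy
(zero information, default reward) and the shortest path (maximal reward at
the minimal information able to achieve it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from infonav.maze import (
    ACTIONS,
    DefaultPolicy,
    MazeError,
    MazeMDP,
    Policy,
    policy_value_vector,
    shortest_path_value,
    _check_proper,
)

DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 100_000


class ConvergenceError(RuntimeError):
    """Raised when the fixed-point iteration fails to converge."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


def default_beta_grid(
    n: int = 60, beta_min: float = 1e-3, beta_max: float = 1e3
) -> np.ndarray:
    """``{0}`` followed by geometrically spaced betas; includes the limits."""
    return np.concatenate([[0.0], np.geomspace(beta_min, beta_max, n)])


def per_state_control_info(policy_at_s, default_at_s) -> float:
    """KL divergence (nats) of a single state's policy from the default.

    Both arguments are probability vectors over the same action set
    (sequences or mappings in matching order).  ``0 * log 0`` is treated
    as 0; support of the policy outside the default's support is an
    infinite control cost and raises.
    """
    p = np.asarray(list(policy_at_s.values()) if isinstance(policy_at_s, dict) else policy_at_s, dtype=float)
    q = np.asarray(list(default_at_s.values()) if isinstance(default_at_s, dict) else default_at_s, dtype=float)
    if p.shape != q.shape:
        raise ValueError("policy and default vectors have different lengths")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise MazeError("infinite control cost")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


@dataclass
class FreeEnergySolution:
    """Fixed point of the soft Bellman equation at one beta."""

    beta: float
    free_energy: dict[int, float]
    policy: Policy
    converged: bool
    iterations: int
    residual: float


@dataclass
class TradeoffPoint:
    """One (control information, value) point, typically for a solved beta."""

    beta: float | None
    control_info: float
    value: float


@dataclass
class Frontier:
    """Ordered optimal trade-off curve for one start/goal pair."""

    start: int
    goal: int
    points: list[TradeoffPoint]
    epsilon: float | None = None

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        i = np.array([p.control_info for p in self.points])
        v = np.array([p.value for p in self.points])
        return i, v

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "beta": [p.beta for p in self.points],
                "control_info_nats": [p.control_info for p in self.points],
                "value_steps": [p.value for p in self.points],
            }
        )


def _log_default(mdp: MazeMDP, default: Policy) -> np.ndarray:
    rho = default.as_array(mdp.states)
    with np.errstate(divide="ignore"):
        return np.where(mdp.valid, np.log(np.where(rho > 0, rho, 1.0)), -np.inf), rho


def solve_free_energy(
    mdp: MazeMDP,
    default: DefaultPolicy | Policy,
    beta: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FreeEnergySolution:
    """Iterate the soft Bellman operator to its fixed point F*(s; beta).

    The iteration starts from F = 0 and stops when the sup-norm change
    drops below ``tol``.  A max-shifted log-sum-exp keeps the update stable
    at large beta.  At beta = 0 the fixed point is F* = 0 and the optimal
    policy is the default policy itself.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    logrho, rho = _log_default(mdp, default)
    n = mdp.n_states
    gi = mdp.index(mdp.goal)
    # beta * R: -beta per step outside the goal
    bR = np.full((n, len(ACTIONS)), -beta)
    bR[gi, :] = 0.0
    base = np.where(mdp.valid, logrho + bR, -np.inf)
    F = np.zeros(n)
    residual = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = base - F[mdp.succ_idx]
        M[~mdp.valid] = -np.inf
        mmax = M.max(axis=1)
        F_new = -(mmax + np.log(np.exp(M - mmax[:, None]).sum(axis=1)))
        F_new[gi] = 0.0
        residual = float(np.max(np.abs(F_new - F)))
        F = F_new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"free-energy iteration did not converge at beta={beta}", residual
        )
    # Boltzmann policy: pi*(a|s) = rho exp(beta R - F(succ)) / exp(-F*(s))
    M = base - F[mdp.succ_idx]
    M[~mdp.valid] = -np.inf
    logpi = M + F[:, None]
    pi = np.where(mdp.valid, np.exp(logpi), 0.0)
    pi /= pi.sum(axis=1, keepdims=True)
    probs = {
        s: {a: float(pi[mdp.index(s), j]) for j, a in enumerate(ACTIONS) if mdp.valid[mdp.index(s), j]}
        for s in mdp.states
    }
    return FreeEnergySolution(
        beta=float(beta),
        free_energy={s: float(F[mdp.index(s)]) for s in mdp.states},
        policy=Policy(probs, mdp.graph),
        converged=converged,
        iterations=it,
        residual=residual,
    )


def control_info_vector(
    mdp: MazeMDP, default: Policy, policy: Policy
) -> np.ndarray:
    """Expected cumulative control information I(s; pi) for every state.

    Solves the linear accumulation ``I(s) = dI(s; pi) + sum_a pi(a|s)
    I(P(s,a))`` with ``I(goal) = 0`` exactly.
    """
    n = mdp.n_states
    gi = mdp.index(mdp.goal)
    dI = np.zeros(n)
    P = np.zeros((n, n))
    for s in mdp.states:
        i = mdp.index(s)
        if s == mdp.goal:
            continue
        acts = mdp.actions(s)
        dI[i] = per_state_control_info(
            [policy.prob(s, a) for a in acts], [default.prob(s, a) for a in acts]
        )
        for a in acts:
            p = policy.prob(s, a)
            if p > 0:
                P[i, mdp.index(mdp.successor(s, a))] += p
    nong = [i for i in range(n) if i != gi]
    I = np.zeros(n)
    Q = P[np.ix_(nong, nong)]
    I[nong] = np.linalg.solve(np.eye(len(nong)) - Q, dI[nong])
    return I


def evaluate_info_value(
    mdp: MazeMDP,
    default: Policy,
    policy: Policy,
    start: int,
    beta: float | None = None,
) -> TradeoffPoint:
    """Exact (control information, value) of a proper policy from ``start``."""
    _check_proper(mdp, policy, start)
    V = policy_value_vector(mdp, policy)
    I = control_info_vector(mdp, default, policy)
    i0 = mdp.index(start)
    return TradeoffPoint(beta=beta, control_info=float(I[i0]), value=float(V[i0]))


def compute_frontier(
    mdp: MazeMDP,
    default: DefaultPolicy | Policy,
    start: int,
    beta_grid=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Frontier:
    """Solve the trade-off at every beta of the grid and assemble the frontier.

    The leftmost point (beta = 0) is ``(0, V_rho(start))``; the rightmost
    value should equal the shortest-path value when the largest beta is
    large enough (a warning is emitted otherwise).
    """
    if beta_grid is None:
        beta_grid = default_beta_grid()
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(beta_grid < 0) or np.any(np.diff(beta_grid) < 0):
        raise ValueError("beta grid must be sorted and non-negative")
    if beta_grid[0] != 0.0:
        raise ValueError("beta grid must include 0")
    points = []
    for beta in beta_grid:
        try:
            sol = solve_free_energy(mdp, default, beta, tol=tol, max_iter=max_iter)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"frontier solve failed at beta={beta}", exc.residual
            ) from exc
        points.append(evaluate_info_value(mdp, default, sol.policy, start, beta=beta))
    eps = getattr(default, "epsilon", None)
    frontier = Frontier(start=start, goal=mdp.goal, points=points, epsilon=eps)
    v_best = shortest_path_value(mdp, start)
    if abs(points[-1].value - v_best) > 1e-6:
        warnings.warn(
            f"largest beta {beta_grid[-1]} does not reach the shortest-path value "
            f"({points[-1].value:.6f} vs {v_best:.6f})",
            stacklevel=2,
        )
    return frontier


def _point_segment_distance(px, py, ax, ay, bx, by) -> float:
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return float(np.hypot(px - ax, py - ay))
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / L2, 0.0, 1.0)
    return float(np.hypot(px - (ax + t * vx), py - (ay + t * vy)))


def frontier_envelope(frontier: Frontier, info: float) -> float:
    """Value of the piecewise-linear optimal envelope at a given information."""
    I, V = frontier.arrays()
    # keep the upper envelope in case of numerically-duplicated I values
    return float(np.interp(info, I, V))


def distance_from_frontier(
    frontier: Frontier,
    point: tuple[float, float],
    info_scale: float = 1.0,
    value_scale: float = 1.0,
    above_tol: float = 1e-4,
) -> float:
    """Euclidean distance from (control_info, value) to the optimal curve.

    The curve is the piecewise-linear interpolation of the frontier points,
    extended horizontally to the right of the last point (any information
    spent beyond the optimum buys no further reward).  Points above the
    envelope by more than ``above_tol`` are unachievable and raise; points
    within the tolerance are snapped onto the curve (distance 0).  The
    default tolerance absorbs the chordal undershoot of the finite beta
    grid: the linear interpolant lies slightly below the true concave
    frontier, so a path that is exactly optimal can sit marginally above
    it.  Optional axis scales let callers measure in units other than raw
    nats/steps.
    """
    info, value = point
    if info < 0:
        raise ValueError("control information must be non-negative")
    env = frontier_envelope(frontier, info)
    if value > env + above_tol:
        raise MazeError("above optimal frontier")
    if value >= env:
        return 0.0
    I, V = frontier.arrays()
    I = I * info_scale
    V = V * value_scale
    px, py = info * info_scale, value * value_scale
    candidates = [
        _point_segment_distance(px, py, I[k], V[k], I[k + 1], V[k + 1])
        for k in range(len(I) - 1)
    ]
    # horizontal extension right of the last point
    if px > I[-1]:
        candidates.append(abs(py - V[-1]))
    else:
        candidates.append(float(np.hypot(px - I[-1], py - V[-1])))
    return min(candidates)
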