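"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: free energies come from
a dense linear solve of the path partition function (probability domain,
not the log-domain fixed point), values from absorption linear algebra
built directly from the policy dictionaries, and path sets from exhaustive
enumeration.
"""

import itertools

import networkx as nx
import numpy as np

from infonav.maze import ACTIONS


def dense_policy_value(graph, policy, goal: int) -> dict[int, float]:
    """V_pi for every state by a direct dense absorption solve."""
    states = graph.node_ids
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    P = np.zeros((n, n))
    for s in states:
        if s == goal:
            continue
        for a, p in policy.dist(s).items():
            if p > 0:
                P[idx[s], idx[graph.neighbor(s, a)]] += p
    keep = [i for i, s in enumerate(states) if s != goal]
    Q = P[np.ix_(keep, keep)]
    v = np.linalg.solve(np.eye(len(keep)) - Q, -np.ones(len(keep)))
    out = {goal: 0.0}
    for k, i in enumerate(keep):
        out[states[i]] = float(v[k])
    return out


def partition_free_energy(graph, default, goal: int, beta: float) -> dict[int, float]:
    """F*(s; beta) = -log sum_paths rho(path) exp(beta * R(path)).

    The path sum over the absorbing chain is a dense linear solve in the
    probability domain: Z = (I - Q)^(-1) b with Q the within-maze flow
    rho * e^(-beta) and b the flow into the goal.
    """
    states = graph.node_ids
    idx = {s: i for i, s in enumerate(states)}
    nong = [s for s in states if s != goal]
    m = len(nong)
    Q = np.zeros((m, m))
    b = np.zeros(m)
    pos = {s: i for i, s in enumerate(nong)}
    w = np.exp(-beta)
    for s in nong:
        for a, p in default.dist(s).items():
            if p <= 0:
                continue
            t = graph.neighbor(s, a)
            if t == goal:
                b[pos[s]] += p * w
            else:
                Q[pos[s], pos[t]] += p * w
    z = np.linalg.solve(np.eye(m) - Q, b)
    out = {goal: 0.0}
    for s in nong:
        out[s] = float(-np.log(z[pos[s]]))
    return out


def enumerate_simple_paths(graph, start: int, goal: int):
    """All simple start->goal paths as (states, actions) pairs."""
    g = graph.to_networkx()
    for states in nx.all_simple_paths(g, start, goal):
        actions = [graph.direction_between(u, v) for u, v in zip(states[:-1], states[1:])]
        yield states, actions


def path_point(default, states, actions) -> tuple[float, float]:
    """(empirical control information, reward) of a deterministic simple
    path: sum of -ln rho along it, and -(length)."""
    info = sum(-np.log(default.prob(s, a)) for s, a in zip(states[:-1], actions))
    return float(info), -float(len(actions))


def brute_force_betweenness(graph) -> dict[int, float]:
    """Endpoint-excluding betweenness by explicit all-pairs shortest-path
    enumeration, normalised by (n-1)(n-2)/2."""
    g = graph.to_networkx()
    nodes = graph.node_ids
    n = len(nodes)
    acc = {s: 0.0 for s in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        for p in paths:
            for v in p[1:-1]:
                acc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {s: acc[s] / norm for s in nodes}


def brute_force_harmonic(graph) -> dict[int, float]:
    g = graph.to_networkx()
    out = {}
    for s in graph.node_ids:
        d = nx.single_source_shortest_path_length(g, s)
        out[s] = sum(1.0 / d[t] for t in d if t != s)
    return out
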