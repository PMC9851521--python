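"""Maze graphs and episodic pathfinding MDPs.

A maze is an undirected 4-neighbour grid graph: nodes carry integer
coordinates, edges carry compass direction labels, and every edge has a
reciprocal partner with the opposite label.  A :class:`MazeMDP` turns the
graph into an episodic MDP with deterministic transitions, a -1 step reward
and an absorbing goal state, which is the substrate for all frontier and
trajectory computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

#: Compass actions in canonical order, with their grid displacement.
ACTIONS: tuple[str, ...] = ("N", "S", "E", "W")
DIRECTION_DELTA: dict[str, tuple[int, int]] = {
    "N": (0, 1),
    "S": (0, -1),
    "E": (1, 0),
    "W": (-1, 0),
}
OPPOSITE: dict[str, str] = {"N": "S", "S": "N", "E": "W", "W": "E"}


class MazeError(ValueError):
    """Raised when a maze graph or MDP invariant is violated."""


@dataclass(frozen=True)
class Node:
    """A maze node on the integer grid."""

    id: int
    x: int
    y: int
    landmark: bool = False
    name: str = ""


class MazeGraph:
    """Validated 4-neighbour maze graph.

    Parameters
    ----------
    nodes:
        Iterable of :class:`Node` (or ``(id, x, y, landmark, name)`` tuples).
    edges:
        Iterable of ``(u, v, direction)`` triples.  Reciprocal edges may be
        given explicitly or are added automatically.
    metadata:
        Free-form mapping (e.g. the default training route).
    """

    def __init__(
        self,
        nodes: Iterable[Node | Sequence],
        edges: Iterable[Sequence],
        metadata: Mapping | None = None,
    ) -> None:
        self.nodes: dict[int, Node] = {}
        for n in nodes:
            if not isinstance(n, Node):
                n = Node(*n)
            if n.id in self.nodes:
                raise MazeError(f"duplicate node id {n.id}")
            if int(n.x) != n.x or int(n.y) != n.y:
                raise MazeError(f"node {n.id} not on the integer grid")
            self.nodes[n.id] = n
        # adjacency[s][direction] -> neighbour id
        self.adjacency: dict[int, dict[str, int]] = {i: {} for i in self.nodes}
        for u, v, d in edges:
            self._add_edge(u, v, d)
            self._add_edge(v, u, OPPOSITE[d])
        self.metadata: dict = dict(metadata or {})
        self._validate()

    def _add_edge(self, u: int, v: int, d: str) -> None:
        if d not in DIRECTION_DELTA:
            raise MazeError(f"unknown direction label {d!r}")
        if u not in self.nodes or v not in self.nodes:
            raise MazeError(f"edge ({u},{v}) references unknown node")
        dx, dy = DIRECTION_DELTA[d]
        nu, nv = self.nodes[u], self.nodes[v]
        if (nu.x + dx, nu.y + dy) != (nv.x, nv.y):
            raise MazeError(
                f"edge ({u},{v},{d}) does not connect 4-neighbours consistently"
            )
        prev = self.adjacency[u].get(d)
        if prev is not None and prev != v:
            raise MazeError(f"node {u} has two edges labelled {d}")
        self.adjacency[u][d] = v

    def _validate(self) -> None:
        for s, nbrs in self.adjacency.items():
            if len(nbrs) > 4:  # pragma: no cover - dict keys bound by labels
                raise MazeError(f"node {s} has more than 4 edges")
            for d, t in nbrs.items():
                if self.adjacency[t].get(OPPOSITE[d]) != s:
                    raise MazeError(f"edge ({s},{t},{d}) lacks a reciprocal edge")
        if len(self.nodes) > 1 and not nx.is_connected(self.to_networkx()):
            raise MazeError("graph not connected")

    # -- convenience accessors -------------------------------------------
    @property
    def node_ids(self) -> list[int]:
        return sorted(self.nodes)

    @property
    def landmark_ids(self) -> list[int]:
        return sorted(i for i, n in self.nodes.items() if n.landmark)

    def coords(self, s: int) -> tuple[int, int]:
        n = self.nodes[s]
        return (n.x, n.y)

    def coord_array(self) -> np.ndarray:
        """``(n, 2)`` array of coordinates in ``node_ids`` order."""
        return np.array([self.coords(s) for s in self.node_ids], dtype=float)

    def degree(self, s: int) -> int:
        return len(self.adjacency[s])

    def actions(self, s: int) -> list[str]:
        """Available compass actions at ``s``, in canonical order."""
        return [a for a in ACTIONS if a in self.adjacency[s]]

    def neighbor(self, s: int, a: str) -> int | None:
        return self.adjacency[s].get(a)

    def direction_between(self, u: int, v: int) -> str | None:
        """Direction label of the edge u->v, or None if not adjacent."""
        for d, t in self.adjacency[u].items():
            if t == v:
                return d
        return None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for s, nbrs in self.adjacency.items():
            for t in nbrs.values():
                g.add_edge(s, t)
        return g

    # -- serialization ----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "x": n.x, "y": n.y, "landmark": n.landmark, "name": n.name}
                for n in (self.nodes[i] for i in self.node_ids)
            ],
            "edges": sorted(
                [s, t, d]
                for s, nbrs in self.adjacency.items()
                for d, t in nbrs.items()
                if s < t
            ),
            "metadata": self.metadata,
        }

    @classmethod
    def from_json_dict(cls, data: Mapping) -> "MazeGraph":
        nodes = [
            Node(
                int(d["id"]),
                int(d["x"]),
                int(d["y"]),
                bool(d.get("landmark", False)),
                str(d.get("name", "")),
            )
            for d in data["nodes"]
        ]
        return cls(nodes, data["edges"], data.get("metadata"))


def load_maze(path) -> MazeGraph:
    """Read and validate a maze JSON file."""
    with open(path) as fh:
        return MazeGraph.from_json_dict(json.load(fh))


def save_maze(graph: MazeGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph.to_json_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# MDP


class MazeMDP:
    """Episodic pathfinding MDP on a maze graph.

    Transitions are deterministic along graph edges, the reward is -1 per
    step everywhere except at the absorbing goal, where every action
    self-transitions with reward 0.
    """

    def __init__(self, graph: MazeGraph, goal: int) -> None:
        if goal not in graph.nodes:
            raise MazeError("goal not in graph")
        self.graph = graph
        self.goal = goal
        self.states = graph.node_ids
        self._index = {s: i for i, s in enumerate(self.states)}
        n = len(self.states)
        # successor index array; goal rows self-transition for every action
        self.succ_idx = np.full((n, len(ACTIONS)), -1, dtype=int)
        self.valid = np.zeros((n, len(ACTIONS)), dtype=bool)
        for s, i in self._index.items():
            for j, a in enumerate(ACTIONS):
                t = graph.neighbor(s, a)
                if t is not None:
                    self.succ_idx[i, j] = self._index[t]
                    self.valid[i, j] = True
        gi = self._index[goal]
        self.succ_idx[gi, :] = gi  # absorbing: every goal action self-loops
        for s in self.states:
            if s != goal and not graph.actions(s):
                raise MazeError(f"state {s} has no available action")

    def index(self, s: int) -> int:
        return self._index[s]

    def actions(self, s: int) -> list[str]:
        return self.graph.actions(s)

    def successor(self, s: int, a: str) -> int:
        """P(.|s,a) support: the deterministic successor (goal is absorbing)."""
        if s == self.goal:
            return self.goal
        t = self.graph.neighbor(s, a)
        if t is None:
            raise MazeError(f"action {a} unavailable at state {s}")
        return t

    def reward(self, s: int, a: str) -> float:
        return 0.0 if s == self.goal else -1.0

    @property
    def n_states(self) -> int:
        return len(self.states)


def build_mdp(graph: MazeGraph, goal: int) -> MazeMDP:
    """Construct the episodic MDP with step reward -1 and absorbing ``goal``."""
    if goal not in graph.nodes:
        raise MazeError("goal not in graph")
    if len(graph.nodes) > 1 and not nx.is_connected(graph.to_networkx()):
        raise MazeError("graph not connected")
    return MazeMDP(graph, goal)


# ---------------------------------------------------------------------------
# Policies


class Policy:
    """Per-state probability distributions over the available actions."""

    def __init__(self, probs: Mapping[int, Mapping[str, float]], graph: MazeGraph):
        self.graph = graph
        self.probs: dict[int, dict[str, float]] = {}
        for s, dist in probs.items():
            avail = set(graph.actions(s))
            total = 0.0
            clean: dict[str, float] = {}
            for a, p in dist.items():
                if p < 0:
                    raise MazeError(f"negative probability at state {s}")
                if p > 0 and a not in avail:
                    raise MazeError(f"policy support outside A({s})")
                clean[a] = float(p)
                total += p
            if abs(total - 1.0) > 1e-9:
                raise MazeError(f"policy at state {s} sums to {total}")
            self.probs[s] = clean

    def prob(self, s: int, a: str) -> float:
        return self.probs[s].get(a, 0.0)

    def dist(self, s: int) -> dict[str, float]:
        return self.probs[s]

    def states(self) -> list[int]:
        return sorted(self.probs)

    def as_array(self, states: Sequence[int]) -> np.ndarray:
        """``(n, 4)`` probability array in canonical action order."""
        out = np.zeros((len(states), len(ACTIONS)))
        for i, s in enumerate(states):
            for j, a in enumerate(ACTIONS):
                out[i, j] = self.prob(s, a)
        return out

    @classmethod
    def uniform(cls, graph: MazeGraph) -> "Policy":
        return cls(
            {
                s: {a: 1.0 / len(graph.actions(s)) for a in graph.actions(s)}
                for s in graph.node_ids
            },
            graph,
        )

    @classmethod
    def deterministic(cls, graph: MazeGraph, choice: Mapping[int, str]) -> "Policy":
        probs = {}
        for s in graph.node_ids:
            if s in choice:
                probs[s] = {choice[s]: 1.0}
            else:
                acts = graph.actions(s)
                probs[s] = {a: 1.0 / len(acts) for a in acts}
        return cls(probs, graph)


class DefaultPolicy(Policy):
    """The habitual training-route policy.

    On route nodes the trained action receives probability ``1 - epsilon``
    and the remaining mass is split over the other available actions; nodes
    the training route never traversed get a uniform distribution.  The
    smoothing mass ``epsilon`` keeps the default policy full-support, so
    that deviating from the route (even travelling it backwards) carries a
    large but finite information cost.
    """

    def __init__(self, graph: MazeGraph, route: Sequence[int], epsilon: float = 0.05):
        if not (0 <= epsilon < 1):
            raise MazeError("epsilon must lie in [0, 1)")
        route_action: dict[int, str] = {}
        for u, v in zip(route[:-1], route[1:]):
            d = graph.direction_between(u, v)
            if d is None:
                raise MazeError(f"route step {u}->{v} is not a graph edge")
            if route_action.get(u, d) != d:
                raise MazeError(f"route visits node {u} with conflicting actions")
            route_action[u] = d
        probs: dict[int, dict[str, float]] = {}
        for s in graph.node_ids:
            acts = graph.actions(s)
            if s in route_action:
                dist = {a: 0.0 for a in acts}
                if len(acts) == 1:
                    dist[route_action[s]] = 1.0
                else:
                    dist[route_action[s]] = 1.0 - epsilon
                    for a in acts:
                        if a != route_action[s]:
                            dist[a] = epsilon / (len(acts) - 1)
            else:
                dist = {a: 1.0 / len(acts) for a in acts}
            probs[s] = dist
        super().__init__(probs, graph)
        self.route = list(route)
        self.epsilon = epsilon
        self.route_action = route_action


# ---------------------------------------------------------------------------
# Exact policy evaluation


def _policy_transition(mdp: MazeMDP, policy: Policy) -> np.ndarray:
    """Dense transition matrix of the Markov chain induced by ``policy``."""
    n = mdp.n_states
    P = np.zeros((n, n))
    for s in mdp.states:
        i = mdp.index(s)
        if s == mdp.goal:
            P[i, i] = 1.0
            continue
        for a, p in policy.dist(s).items():
            if p > 0:
                P[i, mdp.index(mdp.successor(s, a))] += p
    return P


def _check_proper(mdp: MazeMDP, policy: Policy, start: int) -> None:
    """A policy is proper iff the goal is reached with probability 1."""
    support = nx.DiGraph()
    support.add_nodes_from(mdp.states)
    for s in mdp.states:
        if s == mdp.goal:
            continue
        for a, p in policy.dist(s).items():
            if p > 0:
                support.add_edge(s, mdp.successor(s, a))
    reachable = nx.descendants(support, start) | {start}
    # every state reachable from start must itself reach the goal
    reaches_goal = nx.ancestors(support, mdp.goal) | {mdp.goal}
    if not reachable <= reaches_goal:
        raise MazeError("improper policy")


def policy_value_vector(mdp: MazeMDP, policy: Policy) -> np.ndarray:
    """Exact V_pi for every state, by solving the linear system.

    States from which the goal is unreachable under the policy support get
    ``-inf``.
    """
    n = mdp.n_states
    P = _policy_transition(mdp, policy)
    gi = mdp.index(mdp.goal)
    nong = [i for i in range(n) if i != gi]
    Q = P[np.ix_(nong, nong)]
    r = np.full(len(nong), -1.0)
    v = np.full(n, -np.inf)
    v[gi] = 0.0
    # (I - Q) v = r  on the sub-chain that is proper; detect improper parts
    support = nx.DiGraph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(P)
    support.add_edges_from(zip(rows, cols))
    proper = nx.ancestors(support, gi) | {gi}
    idx = [k for k, i in enumerate(nong) if i in proper]
    if idx:
        Qp = Q[np.ix_(idx, idx)]
        vp = np.linalg.solve(np.eye(len(idx)) - Qp, r[idx])
        for k, j in zip(idx, range(len(idx))):
            v[nong[k]] = vp[j]
    return v


def policy_value(mdp: MazeMDP, policy: Policy, start: int) -> float:
    """Expected accumulated reward V_pi(start), i.e. -(expected steps)."""
    _check_proper(mdp, policy, start)
    return float(policy_value_vector(mdp, policy)[mdp.index(start)])


def shortest_path_value(mdp: MazeMDP, start: int) -> float:
    """Optimal value V*(start) = -(BFS distance from start to the goal)."""
    try:
        d = nx.shortest_path_length(mdp.graph.to_networkx(), start, mdp.goal)
    except nx.NetworkXNoPath as exc:  # pragma: no cover - connected graphs
        raise MazeError("no path") from exc
    return -float(d)
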