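"""Graph-theoretic control measures for maze nodes.

Betweenness is the endpoint-excluding shortest-path betweenness,
normalised by (n-1)(n-2)/2.  The "closeness" used alongside it is the
harmonic form — the sum over other nodes of the inverse shortest-path
distance — implemented verbatim; note this is what the network literature
calls *harmonic centrality*, not classical closeness.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from infonav.maze import MazeGraph


def betweenness(graph: MazeGraph) -> dict[int, float]:
    """Normalised shortest-path betweenness (endpoints excluded; multiple
    shortest paths share weight equally)."""
    return {
        s: float(v)
        for s, v in nx.betweenness_centrality(
            graph.to_networkx(), normalized=True
        ).items()
    }


def closeness_harmonic(graph: MazeGraph) -> dict[int, float]:
    """Harmonic closeness: sum_t 1/d(s, t) over all other nodes t."""
    return {s: float(v) for s, v in nx.harmonic_centrality(graph.to_networkx()).items()}


def degree(graph: MazeGraph) -> dict[int, int]:
    """Number of edges at each node (1..4 on a 4-neighbour maze)."""
    return {s: graph.degree(s) for s in graph.node_ids}


def dead_end_states(graph: MazeGraph) -> list[int]:
    """Nodes on dead-end arms (cul-de-sacs), by iterative leaf pruning.

    Every node whose only connection to the rest of the maze is back the
    way it came: the degree-1 tips plus the corridor nodes behind them.
    These states accumulate forced halts and turn-arounds regardless of
    decision processes, and per-state VTE there rests on very few visits,
    so analyses typically exclude them.
    """
    g = graph.to_networkx()
    pruned: list[int] = []
    while True:
        leaves = [s for s in g.nodes if g.degree(s) <= 1]
        if not leaves:
            return sorted(pruned)
        pruned.extend(leaves)
        g.remove_nodes_from(leaves)


def centrality_table(graph: MazeGraph) -> pd.DataFrame:
    """Per-node betweenness, harmonic closeness and degree."""
    b = betweenness(graph)
    c = closeness_harmonic(graph)
    d = degree(graph)
    ids = graph.node_ids
    return pd.DataFrame(
        {
            "node_id": ids,
            "betweenness": [b[s] for s in ids],
            "closeness": [c[s] for s in ids],
            "degree": [d[s] for s in ids],
        }
    )
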