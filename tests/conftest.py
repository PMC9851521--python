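import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from infonav.maze import DefaultPolicy, MazeGraph, Node
from infonav.synthetic import bundled_maze_fixture


def make_line(n: int) -> MazeGraph:
    """Line maze 0-1-...-(n-1) along the x axis."""
    nodes = [Node(i, i, 0) for i in range(n)]
    edges = [(i, i + 1, "E") for i in range(n - 1)]
    return MazeGraph(nodes, edges)


def make_plus() -> MazeGraph:
    """Plus maze: center 0 with 4 unit arms (N=1, S=2, E=3, W=4)."""
    nodes = [Node(0, 1, 1), Node(1, 1, 2), Node(2, 1, 0), Node(3, 2, 1), Node(4, 0, 1)]
    edges = [(0, 1, "N"), (0, 2, "S"), (0, 3, "E"), (0, 4, "W")]
    return MazeGraph(nodes, edges)


def make_cycle4() -> MazeGraph:
    """4-cycle on the unit square."""
    nodes = [Node(0, 0, 0), Node(1, 1, 0), Node(2, 1, 1), Node(3, 0, 1)]
    edges = [(0, 1, "E"), (1, 2, "N"), (2, 3, "W"), (3, 0, "S")]
    return MazeGraph(nodes, edges)


def make_y_maze() -> tuple[MazeGraph, DefaultPolicy, int, int]:
    """Two routes from start to goal: a 6-step trained loop (the default
    route) and a 2-step shortcut.  Returns (graph, default, start, goal)."""
    coords = {
        0: (0, 0),  # start
        1: (1, 0),
        2: (2, 0),  # goal
        3: (0, 1),
        4: (1, 1),
        5: (2, 1),
        6: (3, 1),
        7: (3, 0),
    }
    nodes = [Node(i, *c) for i, c in coords.items()]
    edges = [
        (0, 1, "E"),
        (1, 2, "E"),
        (0, 3, "N"),
        (3, 4, "E"),
        (4, 5, "E"),
        (5, 6, "E"),
        (6, 7, "S"),
        (7, 2, "W"),
    ]
    graph = MazeGraph(nodes, edges)
    route = [0, 3, 4, 5, 6, 7, 2]  # 6 steps, the long way round
    return graph, DefaultPolicy(graph, route, epsilon=0.05), 0, 2


@pytest.fixture(scope="session")
def fixture_maze():
    """The bundled 66-node maze and its smoothed training-route policy."""
    return bundled_maze_fixture()


@pytest.fixture
def line5() -> MazeGraph:
    return make_line(5)


@pytest.fixture
def plus_maze() -> MazeGraph:
    return make_plus()


@pytest.fixture
def y_maze():
    return make_y_maze()
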