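"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: shortest
information distances are recomputed by exhaustive enumeration of simple
paths (hop distances are nonnegative, so some shortest path is simple),
and NDCG/conductance checks use direct hand arithmetic in the tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from idgba.graph_core import WeightedGraph


def brute_force_information_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs information distance by exhaustive simple-path enumeration.

    Independent of the package's Dijkstra path: transition probabilities
    and per-hop self-information are recomputed from scratch and every
    simple path is enumerated with a DFS.  Only feasible for tiny graphs.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    deg = w.sum(axis=1)
    hop = np.full((n, n), math.inf)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0 and deg[i] > 0:
                hop[i, j] = -math.log2(w[i, j] / deg[i])
    best = np.full((n, n), math.inf)
    np.fill_diagonal(best, 0.0)

    def dfs(start: int, node: int, visited: set[int], cost: float) -> None:
        for nxt in range(n):
            if nxt in visited or not math.isfinite(hop[node, nxt]):
                continue
            c = cost + hop[node, nxt]
            if c < best[start, nxt]:
                best[start, nxt] = c
            dfs(start, nxt, visited | {nxt}, c)

    for start in range(n):
        dfs(start, start, {start}, 0.0)
    return best


def random_small_graph(rng: np.random.Generator) -> WeightedGraph:
    """A random directed graph on 2..8 nodes; some instances disconnected."""
    n = int(rng.integers(2, 9))
    density = float(rng.uniform(0.1, 0.7))
    w = np.where(rng.random((n, n)) < density, rng.uniform(0.2, 3.0, (n, n)), 0.0)
    np.fill_diagonal(w, 0.0)
    labels = tuple(f"n{i}" for i in range(n))
    return WeightedGraph(labels, w, directed=True)


@pytest.fixture
def triangle() -> WeightedGraph:
    """Unit-weight K_3 on labels A, B, C."""
    w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return WeightedGraph(("A", "B", "C"), w)


@pytest.fixture
def chain3() -> WeightedGraph:
    """Unit-weight path A - B - C."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return WeightedGraph(("A", "B", "C"), w)


@pytest.fixture
def chain4() -> WeightedGraph:
    """Unit-weight path A - B - C - D."""
    w = np.zeros((4, 4))
    for i in range(3):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return WeightedGraph(("A", "B", "C", "D"), w)


@pytest.fixture
def two_triangles() -> WeightedGraph:
    """Two disjoint unit-weight triangles: {A,B,C} and {D,E,F}."""
    w = np.zeros((6, 6))
    for block in ((0, 1, 2), (3, 4, 5)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return WeightedGraph(("A", "B", "C", "D", "E", "F"), w)


def complete_graph(n: int) -> WeightedGraph:
    """Unit-weight K_n with zero-padded labels."""
    w = np.ones((n, n)) - np.eye(n)
    labels = tuple(f"k{i:03d}" for i in range(n))
    return WeightedGraph(labels, w)
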