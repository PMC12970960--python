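"""Weighted-graph data model and file I/O shared by all other modules.

The graph universe is a node-labelled, nonnegatively weighted adjacency
matrix.  Node identity is the string label; every matrix in the package is
indexed by the canonical label order fixed at read/construction time
(header order for adjacency CSV input, sorted lexicographically otherwise).

Self-loops are permitted and contribute to a node's degree like any other
edge; the synthetic generators never emit them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeightedGraph",
    "SeedSet",
    "read_graph",
    "write_graph",
    "read_seed_set",
    "degree",
    "neighbors_outside",
]


@dataclass(frozen=True)
class WeightedGraph:
    """A node-labelled graph with a dense nonnegative weight matrix.

    Parameters
    ----------
    node_labels : tuple of str
        Unique node labels; position fixes the matrix index of each node.
    weights : ndarray of shape (n, n)
        ``weights[i, j]`` is the edge weight from node *i* to node *j*;
        absent edges are exactly 0.  All entries must be >= 0.
    directed : bool
        If False, ``weights`` must be symmetric.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    directed: bool = False
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.node_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] != len(labels):
            raise ValueError(
                f"{len(labels)} labels but {w.shape[0]}x{w.shape[1]} weight matrix"
            )
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        if (w < 0).any():
            raise ValueError("negative edge weight")
        if not self.directed and not np.allclose(w, w.T, rtol=0.0, atol=1e-12):
            raise ValueError("undirected graph requires a symmetric weight matrix")
        object.__setattr__(self, "node_labels", labels)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(labels)})

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def indices_of(self, labels) -> np.ndarray:
        return np.array([self.index_of(x) for x in labels], dtype=int)

    def degree(self, label: str) -> float:
        """Weighted out-degree: the row sum of the weight matrix."""
        return float(self.weights[self.index_of(label)].sum())

    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.node_labels), columns=list(self.node_labels)
        )


@dataclass(frozen=True)
class SeedSet:
    """A nonempty strict subset of a host graph's nodes to be extended."""

    members: frozenset[str]

    @classmethod
    def from_labels(cls, graph: WeightedGraph, labels) -> "SeedSet":
        members = frozenset(str(x) for x in labels)
        if not members:
            raise ValueError("seed set is empty")
        unknown = members - set(graph.node_labels)
        if unknown:
            raise KeyError(f"seed labels not in graph: {sorted(unknown)}")
        if len(members) == len(graph.node_labels):
            raise ValueError("seed set equals the whole graph; extension undefined")
        return cls(members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def _graph_from_edges(edges: pd.DataFrame, directed: bool) -> WeightedGraph:
    src = edges.iloc[:, 0].astype(str)
    tgt = edges.iloc[:, 1].astype(str)
    wt = pd.to_numeric(edges.iloc[:, 2], errors="raise").astype(float)
    if (wt < 0).any():
        bad = edges[wt < 0].iloc[0]
        raise ValueError(f"negative edge weight on ({bad.iloc[0]}, {bad.iloc[1]})")
    labels = sorted(set(src) | set(tgt))
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for s, t, v in zip(src, tgt, wt):
        w[idx[s], idx[t]] = v
        if not directed:
            w[idx[t], idx[s]] = v
    return WeightedGraph(tuple(labels), w, directed=directed)


def read_graph(
    path: str | os.PathLike,
    format: str = "edge-list",
    directed: bool = False,
    header: bool = False,
) -> WeightedGraph:
    """Read a graph from an edge list (TSV) or an adjacency matrix (CSV).

    Edge-list dialect: ``source<TAB>target<TAB>weight``, no header unless
    ``header=True``.  For undirected input each listed edge populates both
    directions.  Adjacency dialect: CSV with node labels as both the first
    row and the first column.
    """
    if format == "edge-list":
        edges = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
        if edges.shape[1] != 3:
            raise ValueError(f"edge list needs 3 columns, got {edges.shape[1]}")
        return _graph_from_edges(edges, directed)
    if format == "adjacency-csv":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.columns]
        row_labels = [str(x) for x in df.index]
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"adjacency matrix is not square: {df.shape}")
        if labels != row_labels:
            raise ValueError("adjacency row labels do not match column labels")
        return WeightedGraph(tuple(labels), df.to_numpy(dtype=float), directed=directed)
    raise ValueError(f"unknown graph format: {format!r}")


def write_graph(
    graph: WeightedGraph, path: str | os.PathLike, format: str = "edge-list"
) -> None:
    """Write a graph; inverse of :func:`read_graph` up to float formatting."""
    if format == "edge-list":
        rows = []
        w = graph.weights
        for i, a in enumerate(graph.node_labels):
            for j, b in enumerate(graph.node_labels):
                if w[i, j] > 0 and (graph.directed or i <= j):
                    rows.append(f"{a}\t{b}\t{float(w[i, j])!r}\n")
        with open(path, "w") as fh:
            fh.writelines(rows)
    elif format == "adjacency-csv":
        graph.to_dataframe().to_csv(path)
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def read_seed_set(path: str | os.PathLike, graph: WeightedGraph) -> SeedSet:
    """Read a seed set: UTF-8 text, one label per line, ``#`` comments ignored."""
    labels = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                labels.append(line)
    return SeedSet.from_labels(graph, labels)


def degree(graph: WeightedGraph, node: str) -> float:
    """Weighted out-degree of ``node`` (sum of its outgoing edge weights)."""
    return graph.degree(node)


def neighbors_outside(graph: WeightedGraph, seeds: SeedSet, node: str) -> bool:
    """True iff ``node`` (a seed member) has an edge to some node outside the set."""
    if node not in seeds.members:
        raise ValueError(f"{node!r} is not a member of the seed set")
    i = graph.index_of(node)
    outside = [j for j, lab in enumerate(graph.node_labels) if lab not in seeds.members]
    return bool((graph.weights[i, outside] > 0).any())
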