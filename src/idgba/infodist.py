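"""Thresholded information distance on weighted networks.

The ease of passing information from node *i* to node *j* is modelled by a
Markov walker on the row-normalized adjacency matrix.  The self-information
of a one-step transition, ``ihd(i, j) = -log2 p_ij`` (bits), turns transition
probabilities into hop distances; the information distance ``id(i, j)`` is
the minimum total hop distance over all directed paths from *i* to *j*.

Under a null model with no structural connectivity, the optimal code names
any node with an equal-length codeword of ``log2(|V|)`` bits.  Distances at
or above this threshold therefore indicate connections no better than
random, and the thresholded information distance caps every distance there:
``idt(i, j) = min(id(i, j), log2(|V|))``.

All logarithms are base 2; all distances are in bits.  Row normalization
makes transitions asymmetric even for undirected input, so ``id`` is a
directed quantity and is never symmetrized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .graph_core import WeightedGraph

__all__ = [
    "TransitionMatrix",
    "HopDistanceMatrix",
    "DistanceBundle",
    "transition_matrix",
    "hop_distances",
    "information_distances",
    "equal_length_threshold",
    "thresholded_distances",
    "distance_bundle",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-step transition probabilities of a graph walker.

    Rows of zero-degree (isolated) nodes are identically zero; their labels
    are listed in ``isolated``.
    """

    probs: np.ndarray
    graph: WeightedGraph
    isolated: tuple[str, ...] = ()


@dataclass(frozen=True)
class HopDistanceMatrix:
    """Per-edge self-information in bits; +inf where there is no edge."""

    ihd: np.ndarray
    graph: WeightedGraph


@dataclass(frozen=True)
class DistanceBundle:
    """Information distances from a set of source nodes to every node.

    ``id_matrix[k, j]`` is the information distance in bits from
    ``sources[k]`` to node *j* (+inf when unreachable); ``idt`` is the
    same matrix capped elementwise at ``threshold`` = log2(|V|).
    """

    sources: tuple[str, ...]
    node_labels: tuple[str, ...]
    id_matrix: np.ndarray
    threshold: float
    idt: np.ndarray

    def idt_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.idt, index=list(self.sources), columns=list(self.node_labels)
        )

    def to_csv(self, path) -> None:
        """Export idt with sources as rows, all nodes as columns, 6 decimals."""
        self.idt_dataframe().to_csv(path, float_format="%.6f")

    def idt_between(self, source: str, target: str) -> float:
        k = self.sources.index(source)
        j = self.node_labels.index(target)
        return float(self.idt[k, j])


def transition_matrix(graph: WeightedGraph) -> TransitionMatrix:
    """Row-normalize the weight matrix into one-step transition probabilities.

    ``p_ij = w_ij / deg(i)``.  Nodes with zero out-degree have an all-zero
    row and are reported as isolated via a warning.
    """
    deg = graph.degrees()
    isolated = tuple(
        lab for lab, d in zip(graph.node_labels, deg) if d == 0.0
    )
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated node(s) with zero degree: "
            f"{list(isolated)[:5]}{'...' if len(isolated) > 5 else ''}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(deg[:, None] > 0, graph.weights / deg[:, None], 0.0)
    return TransitionMatrix(probs=probs, graph=graph, isolated=isolated)


def hop_distances(transitions: TransitionMatrix) -> HopDistanceMatrix:
    """Self-information of each one-step transition: -log2(p), +inf at p=0."""
    p = transitions.probs
    ihd = np.full_like(p, np.inf)
    nz = p > 0
    ihd[nz] = -np.log2(p[nz])
    # -log2 of p slightly above machine-representable 1 would give -0.0
    ihd[nz] = np.maximum(ihd[nz], 0.0)
    return HopDistanceMatrix(ihd=ihd, graph=transitions.graph)


def information_distances(hops: HopDistanceMatrix, sources) -> np.ndarray:
    """Shortest-path distances in information space from each source node.

    Returns a |sources| x |V| matrix of the minimum, over all directed paths,
    of the summed hop distances; +inf for unreachable targets and 0 on the
    diagonal.  Hop distances of exactly 0 bits (deterministic transitions)
    are genuine zero-weight edges and are traversed.
    """
    src = list(sources)
    if not src:
        raise ValueError("empty source set")
    graph = hops.graph
    idx = graph.indices_of(src)
    # csgraph_from_dense with null_value=inf keeps explicit zero-weight edges
    sparse = csgraph.csgraph_from_dense(hops.ihd, null_value=np.inf)
    dist = csgraph.dijkstra(sparse, directed=True, indices=idx)
    return np.atleast_2d(dist)


def equal_length_threshold(n_nodes: int) -> float:
    """Bits needed to name any of ``n_nodes`` under the equal-length null code."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    return float(np.log2(n_nodes))


def thresholded_distances(id_matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Cap distances at the null-model threshold: min(id, T) elementwise."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return np.minimum(np.asarray(id_matrix, dtype=float), threshold)


def distance_bundle(graph: WeightedGraph, sources) -> DistanceBundle:
    """End-to-end computation: transitions -> hops -> shortest paths -> cap.

    ``sources`` is an ordered collection of node labels; the rows of the
    result follow its order.
    """
    if graph.n_nodes < 2:
        raise ValueError("graph must have at least 2 nodes")
    src = tuple(str(s) for s in sources)
    trans = transition_matrix(graph)
    hops = hop_distances(trans)
    id_matrix = information_distances(hops, src)
    threshold = equal_length_threshold(graph.n_nodes)
    idt = thresholded_distances(id_matrix, threshold)
    return DistanceBundle(
        sources=src,
        node_labels=graph.node_labels,
        id_matrix=id_matrix,
        threshold=threshold,
        idt=idt,
    )
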