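"""Network-propagation baselines: random walk with restart and personalized
PageRank.

Both methods iterate a walker that follows the row-normalized transition
matrix and teleports back to the seed set — with probability ``restart``
per step for RWR, or ``1 - damping`` for PPR.  Mass landing on dangling
(zero out-degree) nodes is redistributed to the teleport vector, the
standard PageRank convention, so probability is conserved at every
iteration.  Under this convention RWR with restart r and PPR with damping
1 - r solve the same fixed point; both parameterizations are exposed
because the surrounding literature uses both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import SeedSet, WeightedGraph
from .infodist import transition_matrix

__all__ = ["PropagationScores", "rwr_scores", "ppr_scores", "rank_by_scores"]


@dataclass(frozen=True)
class PropagationScores:
    """Stationary visit probabilities of a restarting walker."""

    node_labels: tuple[str, ...]
    scores: np.ndarray
    restart_prob: float
    seeds: frozenset[str]
    iterations_used: int
    converged: bool

    def score_of(self, label: str) -> float:
        return float(self.scores[self.node_labels.index(label)])


def _teleport_iteration(
    graph: WeightedGraph,
    seeds: SeedSet,
    restart: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Power-iterate v <- (1-r)(P^T v + dangling mass * e_S) + r e_S."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated nodes are dangling, handled here
        p = transition_matrix(graph).probs
    n = graph.n_nodes
    teleport = np.zeros(n)
    teleport[graph.indices_of(seeds.sorted_members())] = 1.0 / len(seeds.members)
    dangling = graph.degrees() == 0.0

    v = teleport.copy()
    for it in range(1, max_iter + 1):
        leaked = v[dangling].sum()
        v_new = (1.0 - restart) * (p.T @ v + leaked * teleport) + restart * teleport
        delta = np.abs(v_new - v).sum()
        v = v_new
        if delta < tol:
            return v, it, True
    return v, max_iter, False


def rwr_scores(
    graph: WeightedGraph,
    seeds: SeedSet,
    restart_prob: float = 0.15,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> PropagationScores:
    """Random walk with restart: each step restarts at the seeds with
    probability ``restart_prob``; returns stationary visit probabilities."""
    if not 0.0 < restart_prob < 1.0:
        raise ValueError(f"restart_prob must be in (0, 1), got {restart_prob}")
    v, it, ok = _teleport_iteration(graph, seeds, restart_prob, tol, max_iter)
    return PropagationScores(
        node_labels=graph.node_labels,
        scores=v,
        restart_prob=restart_prob,
        seeds=frozenset(seeds.members),
        iterations_used=it,
        converged=ok,
    )


def ppr_scores(
    graph: WeightedGraph,
    seeds: SeedSet,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> PropagationScores:
    """Personalized PageRank with teleport vector uniform over the seeds."""
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    restart = 1.0 - damping
    v, it, ok = _teleport_iteration(graph, seeds, restart, tol, max_iter)
    return PropagationScores(
        node_labels=graph.node_labels,
        scores=v,
        restart_prob=restart,
        seeds=frozenset(seeds.members),
        iterations_used=it,
        converged=ok,
    )


def rank_by_scores(scores: PropagationScores, exclude: SeedSet) -> list[str]:
    """Non-seed nodes sorted by descending score, ties broken by label."""
    pairs = [
        (lab, float(s))
        for lab, s in zip(scores.node_labels, scores.scores)
        if lab not in exclude.members
    ]
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return [lab for lab, _ in pairs]
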