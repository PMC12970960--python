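"""Guilt-by-association subgraph extension ranked by information distance.

Candidate nodes outside a seed subgraph S are ranked by their minimum
thresholded information distance from S's *key points*:

* radial metric — key points are the subgraph center, the member node(s)
  of minimal eccentricity (smallest worst-case idt to the other members);
* boundary metric — key points are the inner boundary, the members with
  at least one neighbor outside S.

A single distance bundle with sources = S supplies both the pairwise
within-S distances (for the center) and the S-to-all distances (for the
ranking); paths are never restricted to stay inside S.  Candidates whose
score reaches the equal-length threshold T = log2(|V|) encode no better
than the null model and fall at or after the automatic cutoff; the cutoff
is strict, admitting only scores < T.

Conductance of S — cut weight leaving S over the smaller of the two
volumes — quantifies how well isolated the subgraph is, and hence how much
trust a guilt-by-association extension deserves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_core import SeedSet, WeightedGraph
from .infodist import DistanceBundle, distance_bundle

__all__ = [
    "RankedExtension",
    "ConductanceResult",
    "subgraph_center",
    "inner_boundary",
    "extend",
    "conductance",
]

METRICS = ("radial", "boundary")


@dataclass(frozen=True)
class RankedExtension:
    """Ordered extension candidates with scores and the automatic cutoff.

    ``candidates`` holds every non-seed node, best (smallest score) first;
    ties are broken by label.  ``cutoff_index`` counts the candidates with
    score strictly below ``threshold``; everything at or after that index
    is no better connected than the null model.
    """

    candidates: tuple[str, ...]
    scores: np.ndarray
    cutoff_index: int
    key_points: tuple[str, ...]
    metric: str
    threshold: float

    @property
    def accepted(self) -> tuple[str, ...]:
        """Candidates admitted by the data-driven cutoff."""
        return self.candidates[: self.cutoff_index]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.candidates) + 1),
                "node": list(self.candidates),
                "score_bits": self.scores,
                "below_threshold": self.scores < self.threshold,
            }
        )


@dataclass(frozen=True)
class ConductanceResult:
    """Conductance phi = cut / min(vol(S), vol(complement)) with its parts."""

    phi: float
    cut_weight: float
    vol_s: float
    vol_complement: float


def subgraph_center(bundle: DistanceBundle, members) -> list[str]:
    """Member node(s) of minimal eccentricity under thresholded distances.

    Eccentricity of member *i* is the maximum idt(i, j) over members *j*.
    All nodes attaining the minimum are returned (sorted by label).
    """
    members = sorted(str(m) for m in members)
    if not members:
        raise ValueError("empty seed set has no center")
    missing = set(members) - set(bundle.sources)
    if missing:
        raise KeyError(f"members not among bundle sources: {sorted(missing)}")
    rows = [bundle.sources.index(m) for m in members]
    cols = [bundle.node_labels.index(m) for m in members]
    within = bundle.idt[np.ix_(rows, cols)]
    ecc = within.max(axis=1)
    best = ecc.min()
    return [m for m, e in zip(members, ecc) if e == best]


def inner_boundary(graph: WeightedGraph, seeds: SeedSet) -> list[str]:
    """Seed members with at least one neighbor outside the seed set.

    May be empty when S is a union of whole connected components, in which
    case no boundary-driven extension is possible.
    """
    inside = graph.indices_of(seeds.sorted_members())
    outside = np.setdiff1d(np.arange(graph.n_nodes), inside)
    has_out = (graph.weights[np.ix_(inside, outside)] > 0).any(axis=1)
    return [graph.node_labels[i] for i, hit in zip(inside, has_out) if hit]


def extend(
    graph: WeightedGraph, seeds: SeedSet, metric: str = "boundary"
) -> RankedExtension:
    """Rank all non-seed nodes for inclusion in the extended subgraph.

    Each candidate's score is its minimum thresholded information distance
    from any key point of the chosen metric.  The returned ranking covers
    every candidate; ``cutoff_index`` marks where scores stop beating the
    equal-length null-model threshold.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    members = seeds.sorted_members()
    bundle = distance_bundle(graph, members)

    if metric == "radial":
        key_points = subgraph_center(bundle, members)
    else:
        key_points = inner_boundary(graph, seeds)
        if not key_points:
            raise ValueError(
                "seed set has no outside neighbors; no extension possible"
            )

    key_rows = [bundle.sources.index(k) for k in key_points]
    candidates = [lab for lab in sorted(graph.node_labels) if lab not in seeds.members]
    cand_cols = [bundle.node_labels.index(c) for c in candidates]
    scores = bundle.idt[np.ix_(key_rows, cand_cols)].min(axis=0)

    order = np.lexsort((np.array(candidates), scores))
    ranked = tuple(candidates[i] for i in order)
    ranked_scores = scores[order]
    cutoff = int((ranked_scores < bundle.threshold).sum())
    return RankedExtension(
        candidates=ranked,
        scores=ranked_scores,
        cutoff_index=cutoff,
        key_points=tuple(key_points),
        metric=metric,
        threshold=bundle.threshold,
    )


def conductance(graph: WeightedGraph, seeds: SeedSet) -> ConductanceResult:
    """Conductance of the seed set within its host graph.

    cut(S) is the total edge weight from S to its complement; vol(S) is the
    total outgoing edge weight of S.  phi = cut / min(vol(S), vol(S-bar)),
    defined as 0 when the smaller volume is 0 (an edgeless side cuts
    nothing).
    """
    inside = graph.indices_of(seeds.sorted_members())
    outside = np.setdiff1d(np.arange(graph.n_nodes), inside)
    if outside.size == 0:
        raise ValueError("seed set covers the whole graph; complement is empty")
    w = graph.weights
    cut = float(w[np.ix_(inside, outside)].sum())
    vol_s = float(w[inside].sum())
    vol_c = float(w[outside].sum())
    denom = min(vol_s, vol_c)
    phi = cut / denom if denom > 0 else 0.0
    return ConductanceResult(
        phi=phi, cut_weight=cut, vol_s=vol_s, vol_complement=vol_c
    )
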