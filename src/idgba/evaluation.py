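"""Hold-out evaluation of extension methods by NDCG over repeated splits.

A known cluster is repeatedly split 80/20; each method sees the 80% as the
seed set and must rank all remaining nodes of the graph.  Ranking quality
is scored with binary-relevance NDCG (relevant = the held-out 20%), which
is 1 exactly when every held-out member occupies the top ranks.  ID-GBA
rankings use the full score ordering — the automatic cutoff is recorded
and scored separately as precision/recall of the below-threshold set — so
NDCG stays comparable with methods that have no cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import ppr_scores, rank_by_scores, rwr_scores
from .gba import conductance, extend
from .graph_core import SeedSet, WeightedGraph

__all__ = ["SplitSpec", "EvaluationReport", "ndcg", "run_splits", "summarize"]

KNOWN_METHODS = ("idgba-boundary", "idgba-radial", "rwr", "ppr")


@dataclass(frozen=True)
class SplitSpec:
    """Repeated hold-out splits of a cluster: train = round(f*|C|) members."""

    cluster: frozenset[str]
    n_splits: int = 10
    train_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    def train_size(self) -> int:
        n = int(round(self.train_fraction * len(self.cluster)))
        return min(max(n, 1), len(self.cluster) - 1)


@dataclass
class EvaluationReport:
    """Per-split NDCG per method plus the cluster's conductance."""

    per_split: pd.DataFrame  # columns: split, method, ndcg, cutoff_precision, cutoff_recall
    cluster_conductance: float
    cluster: frozenset[str] = field(default_factory=frozenset)
    restart_prob: float = 0.15


def ndcg(ranking, relevant) -> float:
    """Binary-relevance normalized discounted cumulative gain in [0, 1].

    DCG sums 1/log2(p+1) over the 1-based positions p of relevant items in
    ``ranking``; the ideal DCG places all |relevant| items first.
    """
    relevant = set(relevant)
    if not relevant:
        raise ValueError("relevant set is empty")
    dcg = sum(
        1.0 / math.log2(p + 1)
        for p, item in enumerate(ranking, start=1)
        if item in relevant
    )
    idcg = sum(1.0 / math.log2(p + 1) for p in range(1, len(relevant) + 1))
    return dcg / idcg


def _split_cluster(cluster, spec: SplitSpec, rng: np.random.Generator):
    members = sorted(cluster)
    n_train = spec.train_size()
    for _ in range(spec.n_splits):
        train = rng.choice(len(members), size=n_train, replace=False)
        train_set = {members[i] for i in train}
        yield train_set, set(members) - train_set


def run_splits(
    graph: WeightedGraph,
    spec: SplitSpec,
    methods=KNOWN_METHODS,
    restart_prob: float = 0.15,
) -> EvaluationReport:
    """Score each method's ranking of held-out cluster members.

    For every split, each method receives the sampled train fraction of the
    cluster as its seed set and produces a full ranking of all other nodes;
    NDCG is computed against the held-out members.  The report also carries
    the whole cluster's conductance in the graph.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(KNOWN_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    cluster = set(spec.cluster)
    if not cluster <= set(graph.node_labels):
        raise KeyError("cluster contains labels not in the graph")
    if len(cluster) - spec.train_size() < 1:
        raise ValueError("cluster too small for a nonempty test set")

    phi = conductance(graph, SeedSet.from_labels(graph, cluster)).phi
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for split_id, (train, test) in enumerate(_split_cluster(cluster, spec, rng)):
        seeds = SeedSet.from_labels(graph, train)
        for method in methods:
            cut_prec = cut_rec = np.nan
            if method.startswith("idgba"):
                ext = extend(graph, seeds, metric=method.split("-", 1)[1])
                ranking = list(ext.candidates)
                accepted = set(ext.accepted)
                if accepted:
                    cut_prec = len(accepted & test) / len(accepted)
                else:
                    cut_prec = 0.0
                cut_rec = len(accepted & test) / len(test)
            elif method == "rwr":
                ranking = rank_by_scores(
                    rwr_scores(graph, seeds, restart_prob=restart_prob), seeds
                )
            else:  # ppr
                ranking = rank_by_scores(
                    ppr_scores(graph, seeds, damping=1.0 - restart_prob), seeds
                )
            rows.append(
                {
                    "split": split_id,
                    "method": method,
                    "ndcg": ndcg(ranking, test),
                    "cutoff_precision": cut_prec,
                    "cutoff_recall": cut_rec,
                }
            )
    per_split = pd.DataFrame(
        rows, columns=["split", "method", "ndcg", "cutoff_precision", "cutoff_recall"]
    )
    return EvaluationReport(
        per_split=per_split,
        cluster_conductance=phi,
        cluster=frozenset(cluster),
        restart_prob=restart_prob,
    )


def summarize(report: EvaluationReport) -> dict[str, pd.DataFrame]:
    """Per-method mean/sd/95% CI of NDCG plus paired t-tests between methods.

    The CI uses the t distribution with n-1 degrees of freedom; with the
    default 10 splits the normal approximation would be anti-conservative.
    """
    df = report.per_split
    n_splits = df["split"].nunique()
    if n_splits < 2:
        raise ValueError("need at least 2 splits to summarize")
    rows = []
    for method, grp in df.groupby("method", sort=True):
        vals = grp.sort_values("split")["ndcg"].to_numpy()
        mean = vals.mean()
        sd = vals.std(ddof=1)
        half = stats.t.ppf(0.975, len(vals) - 1) * sd / math.sqrt(len(vals))
        rows.append(
            {
                "method": method,
                "mean_ndcg": mean,
                "sd": sd,
                "ci95_low": mean - half,
                "ci95_high": mean + half,
            }
        )
    summary = pd.DataFrame(rows)

    pairs = []
    methods = sorted(df["method"].unique())
    wide = df.pivot(index="split", columns="method", values="ndcg")
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            diff = wide[a] - wide[b]
            if np.allclose(diff, 0.0):
                t_stat, p_val = 0.0, 1.0
            else:
                t_stat, p_val = stats.ttest_rel(wide[a], wide[b])
            pairs.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "mean_diff": float(diff.mean()),
                    "t": float(t_stat),
                    "p_value": float(p_val),
                }
            )
    return {"per_method": summary, "paired": pd.DataFrame(pairs)}
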