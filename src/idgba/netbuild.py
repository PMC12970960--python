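"""Graph construction pipelines.

Two graph builders feed the extension algorithm:

* ``differential_precision_graph`` — a case/control differential
  co-expression graph.  Precision (inverse covariance) matrices are
  computed for the control samples and for the pooled case+control
  samples; their difference captures the change in conditional-dependence
  structure attributable to the cases.  The difference is symmetrized and
  its magnitude taken, giving a nonnegative adjacency matrix.
* ``disease_graph`` — a disease/disease association graph whose edges are
  Pearson correlations of per-gene association score vectors, computed
  over the genes where at least one of the pair has a nonzero score,
  negatives clipped to zero, then pruned to the top fraction of edges by
  weight.

``spectral_cluster_select`` partitions a graph with normalized spectral
clustering and returns the cluster of minimum conductance as the starting
module for extension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.covariance import graphical_lasso

from .gba import conductance
from .graph_core import SeedSet, WeightedGraph

__all__ = [
    "ExpressionMatrix",
    "ScoreMatrix",
    "ClusterAssignment",
    "read_expression",
    "normalize_expression",
    "select_top_variable",
    "differential_precision_graph",
    "spectral_cluster_select",
    "disease_graph",
]

#: condition number beyond which covariance inversion is ridge-regularized
_COND_LIMIT = 1e12
#: ridge scale relative to the mean covariance diagonal
_RIDGE_SCALE = 1e-3


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with a case/control label per sample."""

    values: pd.DataFrame  # genes as rows, samples as columns
    conditions: pd.Series  # indexed by sample, values in {"case", "control"}

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene labels")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        cond = self.conditions.reindex(self.values.columns)
        if cond.isna().any():
            missing = list(self.values.columns[cond.isna()])[:5]
            raise ValueError(f"samples without condition labels: {missing}")
        bad = set(cond.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"conditions must be case/control, got {sorted(bad)}")
        if len(set(cond.unique())) < 2:
            raise ValueError("both case and control samples are required")
        object.__setattr__(self, "conditions", cond)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass(frozen=True)
class ScoreMatrix:
    """Genes x diseases association scores, each in [0, 1]."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("association scores must lie in [0, 1]")
        if self.scores.index.duplicated().any() or self.scores.columns.duplicated().any():
            raise ValueError("duplicate gene or disease labels")


@dataclass(frozen=True)
class ClusterAssignment:
    """Spectral clustering result with per-cluster conductance."""

    labels: pd.Series  # gene -> cluster index in 0..k-1
    k: int
    conductances: dict[int, float]
    selected: int  # index of the minimum-conductance cluster

    def members(self, cluster: int) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster])

    @property
    def selected_members(self) -> list[str]:
        return self.members(self.selected)


def read_expression(values_path, annotation_path, sep=",") -> ExpressionMatrix:
    """Load genes x samples CSV/TSV plus a (sample, condition) annotation CSV."""
    values = pd.read_csv(values_path, sep=sep, index_col=0)
    annot = pd.read_csv(annotation_path)
    cond = pd.Series(
        annot.iloc[:, 1].astype(str).values, index=annot.iloc[:, 0].astype(str)
    )
    return ExpressionMatrix(values=values, conditions=cond)


def normalize_expression(x: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples; constant genes are dropped with a warning."""
    if x.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = x.values.std(axis=1, ddof=1)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s)", stacklevel=2
        )
    vals = x.values.loc[~constant]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return ExpressionMatrix(values=z, conditions=x.conditions)


def select_top_variable(x: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the n genes of largest variance across all samples.

    Variance ranking must run on the raw values, before z-scoring (which
    would flatten every gene's variance to 1).  Ties at the boundary keep
    the lexicographically smaller label.
    """
    if n > x.values.shape[0]:
        raise ValueError(f"asked for {n} genes but only {x.values.shape[0]} present")
    var = x.values.var(axis=1, ddof=1)
    order = sorted(x.values.index, key=lambda g: (-var[g], g))
    keep = sorted(order[:n])
    return ExpressionMatrix(values=x.values.loc[keep], conditions=x.conditions)


def _ridge_precision(cov: np.ndarray) -> np.ndarray:
    """Invert a covariance matrix, ridge-regularizing when ill-conditioned."""
    if np.linalg.cond(cov) > _COND_LIMIT:
        cov = cov + _RIDGE_SCALE * float(np.mean(np.diag(cov))) * np.eye(len(cov))
    return np.linalg.inv(cov)


def differential_precision_graph(
    x: ExpressionMatrix, estimator: str = "graphical-lasso", alpha: float | None = None
) -> WeightedGraph:
    """Differential co-expression graph from case/control precision matrices.

    weights = |sym(Prec(case+control) - Prec(control))| with zero diagonal.

    With more genes than samples — the usual situation for expression data
    — the empirical covariance is singular and a plain (ridge) inverse
    amplifies sampling noise in its null space, drowning the differential
    signal.  The default estimator is therefore the graphical lasso, which
    zeroes spurious conditional dependencies.  One *shared* penalty is used
    for both fits so the lasso shrinkage bias cancels in the difference;
    its default follows the sparsistency rate of the pooled sample,
    ``alpha = sqrt(log p / n_total)``.  Set ``estimator="ridge"`` for the
    plain regularized inverse (adequate when samples outnumber genes).
    """
    if estimator not in ("graphical-lasso", "ridge"):
        raise ValueError(f"estimator must be graphical-lasso or ridge, got {estimator!r}")
    controls = x.samples_of("control")
    cases = x.samples_of("case")
    if len(controls) < 3 or len(cases) < 3:
        raise ValueError("need at least 3 samples per condition")
    vals = x.values.to_numpy(dtype=float)
    idx_ctrl = [x.values.columns.get_loc(s) for s in controls]
    cov_ctrl = np.cov(vals[:, idx_ctrl], ddof=1)
    cov_all = np.cov(vals, ddof=1)
    if estimator == "graphical-lasso":
        if alpha is None:
            alpha = float(np.sqrt(np.log(vals.shape[0]) / vals.shape[1]))

        def _precision(cov: np.ndarray) -> np.ndarray:
            with warnings.catch_warnings():
                # near-converged dual gaps are immaterial for |diff| weights
                warnings.simplefilter("ignore")
                return graphical_lasso(cov, alpha=alpha, max_iter=100)[1]

    else:
        _precision = _ridge_precision
    diff = _precision(cov_all) - _precision(cov_ctrl)
    diff = 0.5 * (diff + diff.T)
    weights = np.abs(diff)
    np.fill_diagonal(weights, 0.0)
    return WeightedGraph(tuple(x.genes), weights, directed=False)


def spectral_cluster_select(
    graph: WeightedGraph, k: int, rng_seed: int = 0
) -> ClusterAssignment:
    """Normalized spectral clustering into k clusters; select the one of
    minimum conductance as the starting module."""
    n = graph.n_nodes
    if not 2 <= k < n:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    model = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=rng_seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on disconnected affinity
        assignment = model.fit_predict(graph.weights)
    labels = pd.Series(assignment, index=list(graph.node_labels))
    conductances: dict[int, float] = {}
    for c in sorted(set(assignment)):
        members = list(labels.index[labels == c])
        if len(members) == n:  # degenerate single-cluster outcome
            conductances[c] = float("inf")
            continue
        conductances[c] = conductance(
            graph, SeedSet.from_labels(graph, members)
        ).phi
    selected = min(sorted(conductances), key=lambda c: conductances[c])
    return ClusterAssignment(
        labels=labels, k=k, conductances=conductances, selected=selected
    )


def disease_graph(
    scores: ScoreMatrix, prune_fraction: float = 0.05, estimator: str = "pearson"
) -> WeightedGraph:
    """Disease/disease graph from gene x disease association scores.

    Each pair's weight is the correlation of their gene-score vectors over
    the genes where at least one of the two has a nonzero score, clipped
    below at 0.  Only the top ``prune_fraction`` of positive-weight edges
    (by weight, boundary ties kept) survive pruning.
    """
    if not 0.0 < prune_fraction <= 1.0:
        raise ValueError("prune_fraction must be in (0, 1]")
    if estimator not in ("pearson", "cosine"):
        raise ValueError(f"estimator must be pearson or cosine, got {estimator!r}")
    df = scores.scores
    nonzero = df.columns[(df != 0).any(axis=0)]
    dropped = set(df.columns) - set(nonzero)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} disease(s) with all-zero scores", stacklevel=2
        )
    diseases = list(nonzero)
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases with nonzero scores")
    mat = df[diseases].to_numpy(dtype=float)
    m = len(diseases)
    w = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            support = (mat[:, i] != 0) | (mat[:, j] != 0)
            a, b = mat[support, i], mat[support, j]
            if estimator == "cosine":
                denom = np.linalg.norm(a) * np.linalg.norm(b)
                r = float(a @ b / denom) if denom > 0 else 0.0
            else:
                if support.sum() < 2 or a.std() == 0 or b.std() == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
            w[i, j] = w[j, i] = max(r, 0.0)

    if prune_fraction < 1.0:
        upper = w[np.triu_indices(m, k=1)]
        positive = np.sort(upper[upper > 0])[::-1]
        if positive.size:
            keep = math.ceil(prune_fraction * positive.size)
            cutoff = positive[keep - 1]
            w[w < cutoff] = 0.0
    return WeightedGraph(tuple(diseases), w, directed=False)
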