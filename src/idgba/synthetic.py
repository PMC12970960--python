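"""Synthetic fixtures with known planted structure.

Two generators make the whole pipeline testable offline:

* ``planted_cluster_graph`` — a sparse background graph with one planted
  dense cluster (a planted-partition graph), emulating the well-isolated
  disease module the extension method assumes.  Edge weights are uniform
  rather than unit so that row normalization is nontrivial and the
  asymmetric transition structure is exercised.
* ``planted_expression`` — a case/control expression matrix in which a
  module of genes shares a latent factor in the case samples only,
  emulating a co-regulated disease module.  Values are Gaussian: the
  downstream pipeline consumes z-scores, so count-level realism (library
  size, overdispersion) is deliberately out of scope.

Both generators are bit-reproducible under a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

from .graph_core import WeightedGraph
from .netbuild import ExpressionMatrix

__all__ = [
    "PlantedGraphSpec",
    "PlantedExpressionSpec",
    "planted_cluster_graph",
    "planted_expression",
]


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Planted-partition graph: one dense cluster against a sparse background.

    Defaults give a 300-node graph with a 30-node cluster whose internal
    edge probability (0.3) dominates the background rate (0.01) by 30x —
    a strongly isolated module with conductance well below 0.2.
    """

    n_nodes: int = 300
    cluster_size: int = 30
    p_in: float = 0.3
    p_out: float = 0.01
    weight_low: float = 0.5
    weight_high: float = 1.5
    rng_seed: int = 0
    connect: bool = True  # repair disconnected graphs with weight_low bridges

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 2 <= self.cluster_size < self.n_nodes:
            raise ValueError("require 2 <= cluster_size < n_nodes")
        if not 0 < self.weight_low <= self.weight_high:
            raise ValueError("require 0 < weight_low <= weight_high")


@dataclass(frozen=True)
class PlantedExpressionSpec:
    """Case/control expression with a case-only co-regulated gene module.

    In case samples, module genes are sqrt(rho)*f + sqrt(1-rho)*sigma*eps
    with a shared latent factor f per sample, giving pairwise correlation
    rho / (rho + (1-rho)*sigma^2) — exactly ``module_corr`` at the default
    noise_sd = 1.  Controls and non-module genes are i.i.d. standard
    normal.
    """

    n_genes: int = 500
    n_case: int = 100
    n_control: int = 100
    module_genes: int = 40
    module_corr: float = 0.8
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.module_corr < 1.0:
            raise ValueError("module_corr must be in (0, 1)")
        if self.module_genes > self.n_genes:
            raise ValueError("module_genes cannot exceed n_genes")
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("need at least 3 samples per condition")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def planted_cluster_graph(
    spec: PlantedGraphSpec = PlantedGraphSpec(),
) -> tuple[WeightedGraph, set[str]]:
    """Generate the graph and return it with the planted member label set.

    The planted cluster occupies the first ``cluster_size`` labels.  When
    ``spec.connect`` is true and the sampled graph is disconnected, each
    extra component is bridged to a uniformly chosen node of the growing
    giant component with an edge of weight ``weight_low``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, c = spec.n_nodes, spec.cluster_size
    labels = _labels("v", n)
    in_cluster = np.zeros(n, dtype=bool)
    in_cluster[:c] = True

    prob = np.where(
        in_cluster[:, None] & in_cluster[None, :], spec.p_in, spec.p_out
    )
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < prob[iu]
    wvals = rng.uniform(spec.weight_low, spec.weight_high, size=len(iu[0]))
    w = np.zeros((n, n))
    w[iu[0][present], iu[1][present]] = wvals[present]
    w = w + w.T

    if spec.connect:
        n_comp, comp = csgraph.connected_components(csr_matrix(w), directed=False)
        if n_comp > 1:
            # attach each non-root component to the growing connected core
            core = np.flatnonzero(comp == comp[0]).tolist()
            for cid in range(n_comp):
                if cid == comp[0]:
                    continue
                members = np.flatnonzero(comp == cid)
                a = int(rng.choice(members))
                b = int(rng.choice(core))
                w[a, b] = w[b, a] = spec.weight_low
                core.extend(members.tolist())

    graph = WeightedGraph(tuple(labels), w, directed=False)
    return graph, set(labels[:c])


def planted_expression(
    spec: PlantedExpressionSpec = PlantedExpressionSpec(),
) -> tuple[ExpressionMatrix, set[str]]:
    """Generate the expression matrix and return it with the module gene set."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = _labels("g", spec.n_genes)
    samples = _labels("case_", spec.n_case) + _labels("ctrl_", spec.n_control)
    conditions = pd.Series(
        ["case"] * spec.n_case + ["control"] * spec.n_control, index=samples
    )

    vals = rng.standard_normal((spec.n_genes, spec.n_case + spec.n_control))
    rho = spec.module_corr
    factor = rng.standard_normal(spec.n_case)
    module = slice(0, spec.module_genes)
    vals[module, : spec.n_case] = (
        np.sqrt(rho) * factor[None, :]
        + np.sqrt(1.0 - rho) * spec.noise_sd * vals[module, : spec.n_case]
    )

    matrix = ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=samples),
        conditions=conditions,
    )
    return matrix, set(genes[: spec.module_genes])
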