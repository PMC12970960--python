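"""Expression preprocessing, differential precision graph, cluster selection,
and the disease/disease association graph."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from idgba.graph_core import WeightedGraph
from idgba.netbuild import (
    ExpressionMatrix,
    ScoreMatrix,
    differential_precision_graph,
    disease_graph,
    normalize_expression,
    read_expression,
    select_top_variable,
    spectral_cluster_select,
)
from idgba.synthetic import PlantedExpressionSpec, planted_expression


def _expr(values: np.ndarray, n_case: int) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    cond = pd.Series(
        ["case"] * n_case + ["control"] * (values.shape[1] - n_case), index=samples
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), cond)


class TestNormalize:
    def test_rows_zero_mean_unit_sd(self):
        x = _expr(np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 9.0, 1.0]]), 2)
        z = normalize_expression(x)
        assert np.allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_gene_dropped_with_warning(self):
        x = _expr(np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]]), 2)
        with pytest.warns(UserWarning, match="constant"):
            z = normalize_expression(x)
        assert z.genes == ["g1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = _expr(rng.standard_normal((5, 8)), 4)
        once = normalize_expression(x)
        twice = normalize_expression(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)


class TestTopVariable:
    def test_identity_when_n_is_all(self):
        rng = np.random.default_rng(1)
        x = _expr(rng.standard_normal((4, 6)), 3)
        assert select_top_variable(x, 4).genes == x.genes

    def test_keeps_largest_variances(self):
        vals = np.vstack(
            [np.array([0, 0, 1, -1.0]) * s for s in (1.0, math.sqrt(2), math.sqrt(3))]
        )
        x = _expr(vals, 2)
        assert select_top_variable(x, 2).genes == ["g1", "g2"]

    def test_tie_keeps_smaller_label(self):
        vals = np.vstack([np.array([1.0, -1, 0, 0])] * 3)
        x = _expr(vals, 2)
        assert select_top_variable(x, 2).genes == ["g0", "g1"]

    def test_too_many_requested(self):
        x = _expr(np.zeros((3, 4)), 2)
        with pytest.raises(ValueError):
            select_top_variable(x, 5)


class TestDifferentialPrecision:
    def test_output_is_valid_graph(self):
        x, _ = planted_expression(
            PlantedExpressionSpec(n_genes=30, n_case=40, n_control=40, module_genes=8)
        )
        g = differential_precision_graph(x)
        assert np.allclose(g.weights, g.weights.T)
        assert (g.weights >= 0).all()
        assert np.all(np.diag(g.weights) == 0)

    def test_null_data_weights_shrink_with_sample_size(self):
        """Same-distribution case/control: weights concentrate near zero as
        the sample count grows (ridge path, well-conditioned regime)."""
        rng = np.random.default_rng(3)
        medians = []
        for n in (30, 300):
            vals = rng.standard_normal((10, 2 * n))
            g = differential_precision_graph(_expr(vals, n), estimator="ridge")
            medians.append(np.median(g.weights[np.triu_indices(10, 1)]))
        assert medians[1] < medians[0]
        assert medians[1] < 0.1

    def test_case_only_coupled_pair_is_heaviest(self):
        """A gene pair correlated only in cases tops the edge weights."""
        x, truth = planted_expression(
            PlantedExpressionSpec(
                n_genes=12, n_case=150, n_control=150, module_genes=2, module_corr=0.8
            )
        )
        g = differential_precision_graph(x, estimator="ridge")
        i, j = g.indices_of(sorted(truth))
        triu = np.triu_indices(g.n_nodes, 1)
        assert g.weights[i, j] == g.weights[triu].max()

    def test_too_few_samples_rejected(self):
        x = _expr(np.random.default_rng(0).standard_normal((4, 5)), 2)
        with pytest.raises(ValueError, match="at least 3"):
            differential_precision_graph(x)


class TestSpectralSelect:
    @staticmethod
    def _two_blocks() -> WeightedGraph:
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        np.fill_diagonal(w, 0.0)
        return WeightedGraph(tuple(f"n{i}" for i in range(10)), w)

    def test_disjoint_blocks_recovered(self):
        g = self._two_blocks()
        a = spectral_cluster_select(g, k=2, rng_seed=0)
        groups = {frozenset(a.members(c)) for c in (0, 1)}
        assert groups == {
            frozenset(f"n{i}" for i in range(5)),
            frozenset(f"n{i}" for i in range(5, 10)),
        }
        assert all(phi == 0.0 for phi in a.conductances.values())

    def test_deterministic_under_seed(self):
        g = self._two_blocks()
        a = spectral_cluster_select(g, k=2, rng_seed=5)
        b = spectral_cluster_select(g, k=2, rng_seed=5)
        assert a.labels.equals(b.labels)

    def test_every_gene_assigned_at_max_k(self):
        g = self._two_blocks()
        a = spectral_cluster_select(g, k=9, rng_seed=0)
        assert len(a.labels) == 10
        assert set(a.labels) <= set(range(9))

    def test_k_out_of_range(self):
        g = self._two_blocks()
        with pytest.raises(ValueError):
            spectral_cluster_select(g, k=1)
        with pytest.raises(ValueError):
            spectral_cluster_select(g, k=10)

    def test_planted_module_selected(self):
        """Minimum-conductance cluster matches the planted expression module."""
        x, truth = planted_expression(PlantedExpressionSpec(rng_seed=0))
        x = normalize_expression(select_top_variable(x, x.values.shape[0]))
        g = differential_precision_graph(x)
        a = spectral_cluster_select(g, k=5, rng_seed=0)
        sel = set(a.selected_members)
        jac = len(sel & truth) / len(sel | truth)
        assert jac >= 0.8


class TestDiseaseGraph:
    def test_identical_vectors_weight_one(self):
        df = pd.DataFrame(
            {"d1": [0.2, 0.8, 0.0], "d2": [0.2, 0.8, 0.0], "d3": [0.9, 0.0, 0.1]},
            index=["g1", "g2", "g3"],
        )
        g = disease_graph(ScoreMatrix(df), prune_fraction=1.0)
        i, j = g.index_of("d1"), g.index_of("d2")
        assert g.weights[i, j] == pytest.approx(1.0)

    def test_negative_correlation_clipped(self):
        df = pd.DataFrame(
            {"d1": [1.0, 0.0, 0.5], "d2": [0.0, 1.0, 0.5]}, index=["g1", "g2", "g3"]
        )
        g = disease_graph(ScoreMatrix(df), prune_fraction=1.0)
        assert (g.weights >= 0).all()

    def test_prune_keeps_top_fraction(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.uniform(0, 1, (30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"d{i}" for i in range(10)],
        )
        full = disease_graph(ScoreMatrix(df), prune_fraction=1.0)
        pruned = disease_graph(ScoreMatrix(df), prune_fraction=0.05)
        n_pos = (full.weights[np.triu_indices(10, 1)] > 0).sum()
        n_kept = (pruned.weights[np.triu_indices(10, 1)] > 0).sum()
        assert n_kept == math.ceil(0.05 * n_pos)
        # surviving edges are the heaviest ones
        kept = pruned.weights[pruned.weights > 0]
        zeroed = full.weights[(full.weights > 0) & (pruned.weights == 0)]
        assert kept.min() >= zeroed.max()

    def test_all_zero_disease_excluded(self):
        df = pd.DataFrame(
            {"d1": [0.5, 0.1], "d2": [0.4, 0.2], "d3": [0.0, 0.0]},
            index=["g1", "g2"],
        )
        with pytest.warns(UserWarning, match="all-zero"):
            g = disease_graph(ScoreMatrix(df), prune_fraction=1.0)
        assert "d3" not in g.node_labels

    def test_scores_outside_unit_interval_rejected(self):
        df = pd.DataFrame({"d1": [1.2], "d2": [0.1]}, index=["g1"])
        with pytest.raises(ValueError):
            ScoreMatrix(df)


class TestIO:
    def test_read_expression_round_trip(self, tmp_path):
        x, _ = planted_expression(
            PlantedExpressionSpec(n_genes=6, n_case=3, n_control=4, module_genes=2)
        )
        vp, ap = tmp_path / "x.csv", tmp_path / "annot.csv"
        x.values.to_csv(vp)
        pd.DataFrame(
            {"sample": x.conditions.index, "condition": x.conditions.values}
        ).to_csv(ap, index=False)
        back = read_expression(vp, ap)
        assert back.genes == x.genes
        assert np.allclose(back.values, x.values)
        assert back.conditions.equals(x.conditions)
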