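"""Mass-action affinities, co-expression weights and feature assembly."""

import numpy as np
import pytest
from scipy.stats import rankdata

from edgemarker.io import ExpressionMatrix, ValidationError
from edgemarker.features import (
    InteractionNetwork,
    MassActionParams,
    anchor_edge_filter,
    assemble_features,
    class_centroids,
    mass_action_affinity,
    spearman_coexpression,
    threshold_coexpression,
)
from edgemarker.lp import ModelParams, build_lp, solve_lp


def expr_from(values, labels=None, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, labels)


class TestMassActionAffinity:
    @pytest.mark.parametrize(
        "xu, xv, params, expected",
        [
            (2.0, 3.0, MassActionParams(), 6.0),
            (0.0, 5.0, MassActionParams(), 0.0),
            (2.0, 3.0, MassActionParams(0.5, 2.0, 1.0), 6.0),  # 0.5 * 4 * 3
        ],
    )
    def test_pointwise_affinity(self, xu, xv, params, expected):
        expr = expr_from([[xu], [xv]], genes=["u", "v"])
        # single-sample matrix: affinity of the only edge in the only sample
        net = InteractionNetwork.from_pairs([("u", "v")])
        aff = mass_action_affinity(expr, net, params)
        assert aff.values[0, 0] == pytest.approx(expected)

    def test_symmetric_under_default_stoichiometry(self, rng):
        expr = expr_from(rng.random((2, 8)) + 0.1, genes=["u", "v"])
        fwd = mass_action_affinity(expr, InteractionNetwork([("u", "v")]))
        rev = mass_action_affinity(expr, InteractionNetwork([("v", "u")]))
        np.testing.assert_allclose(fwd.values, rev.values)

    def test_missing_endpoint_names_the_edge(self, small_expr):
        net = InteractionNetwork([("gA", "gZ")])
        with pytest.raises(ValidationError, match="gZ"):
            mass_action_affinity(small_expr, net)


class TestNetwork:
    def test_from_pairs_drops_self_loops_and_duplicates(self):
        net = InteractionNetwork.from_pairs(
            [("b", "a"), ("a", "b"), ("c", "c"), ("a", "c")]
        )
        assert net.edges == [("a", "b"), ("a", "c")]

    def test_anchor_filter_membership(self):
        net = InteractionNetwork([("A", "B"), ("C", "D")])
        assert anchor_edge_filter(net, {"A"}).edges == [("A", "B")]
        assert anchor_edge_filter(net, {"A", "C"}).edges == net.edges

    def test_anchor_filter_empty_anchor_set_raises(self, small_net):
        with pytest.raises(ValidationError):
            anchor_edge_filter(small_net, set())

    def test_anchor_filter_disjoint_warns_and_empties(self, small_net):
        with pytest.warns(UserWarning, match="disjoint"):
            out = anchor_edge_filter(small_net, {"nothing"})
        assert out.n_edges == 0


class TestClassCentroids:
    def test_centroids_are_class_means(self):
        labels = {"s0": "X", "s1": "X", "s2": "Y", "s3": "Y", "s4": "Y"}
        expr = expr_from([[2.0, 4.0, 1.0, 2.0, 6.0], [1.0, 1.0, 1.0, 1.0, 1.0]],
                         labels=labels, genes=["u", "v"])
        aff = mass_action_affinity(expr, InteractionNetwork([("u", "v")]))
        spec = class_centroids(aff, expr)
        assert spec.edge_centroids[0, 0] == pytest.approx(3.0)  # mean(2, 4)
        assert spec.edge_centroids[1, 0] == pytest.approx(3.0)  # mean(1, 2, 6)
        assert spec.node_centroids[0, 0] == pytest.approx(3.0)
        assert spec.sizes == {"X": 2, "Y": 3}

    def test_singleton_class_centroid_is_the_sample(self):
        labels = {"s0": "X", "s1": "Y", "s2": "Y"}
        expr = expr_from([[5.0, 1.0, 3.0]], labels=labels, genes=["u"])
        aff = mass_action_affinity(expr, InteractionNetwork([]))
        spec = class_centroids(aff, expr)
        assert spec.node_centroids[0, 0] == pytest.approx(5.0)


class TestSpearman:
    def test_identical_vectors_give_one(self):
        expr = expr_from([[1.0, 5.0, 3.0], [1.0, 5.0, 3.0]], genes=["u", "v"])
        w = spearman_coexpression(expr, InteractionNetwork([("u", "v")]))
        assert w.raw[0] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        expr = expr_from([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
                         genes=["u", "v"])
        w = spearman_coexpression(expr, InteractionNetwork([("u", "v")]))
        assert w.raw[0] == pytest.approx(-1.0)

    def test_single_swap_three_samples(self):
        # ranks (1,2,3) vs (1,3,2): 1 - 6*2/(3*8) = 0.5
        expr = expr_from([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]], genes=["u", "v"])
        w = spearman_coexpression(expr, InteractionNetwork([("u", "v")]))
        assert w.raw[0] == pytest.approx(0.5)

    def test_literal_formula_denominator_leaves_unit_range(self):
        # reversed order, m=3: sum d^2 = 8, 1 - 48/(3*2) = -7
        expr = expr_from([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], genes=["u", "v"])
        w = spearman_coexpression(
            expr, InteractionNetwork([("u", "v")]), formula_mode="legacy"
        )
        assert w.raw[0] == pytest.approx(-7.0)

    def test_matches_rank_then_pearson_brute_force(self, rng):
        net = InteractionNetwork([("u", "v")])
        for _ in range(200):
            x = rng.permutation(rng.random(9) + 0.01)
            y = rng.permutation(rng.random(9) + 0.01)
            expr = expr_from(np.vstack([x, y]), genes=["u", "v"])
            ours = spearman_coexpression(expr, net).raw[0]
            brute = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert ours == pytest.approx(brute, abs=1e-12)

    def test_constant_gene_zeroed_with_warning(self):
        expr = expr_from([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], genes=["u", "v"])
        with pytest.warns(UserWarning, match="constant"):
            w = spearman_coexpression(expr, InteractionNetwork([("u", "v")]))
        assert w.raw[0] == 0.0 and w.degenerate_edges == [0]

    def test_per_class_max_sees_context_specific_coexpression(self):
        # perfectly correlated in class X, anti-correlated in class Y
        labels = {f"s{j}": ("X" if j < 3 else "Y") for j in range(6)}
        expr = expr_from(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 3.0, 2.0, 1.0]],
            labels=labels, genes=["u", "v"],
        )
        net = InteractionNetwork([("u", "v")])
        pooled = spearman_coexpression(expr, net, scope="pooled").raw[0]
        per_class = spearman_coexpression(expr, net, scope="per_class_max").raw[0]
        assert per_class == pytest.approx(1.0)
        assert abs(pooled) < 0.5


class TestThreshold:
    @pytest.mark.parametrize(
        "raw, k, expected", [(0.6, 0.5, 0.6), (0.4, 0.5, 0.0), (0.3, 0.0, 0.3)]
    )
    def test_cutoff_rule(self, raw, k, expected):
        expr = expr_from([[1.0, 2.0, 3.0]], genes=["u"])
        net = InteractionNetwork([("u", "v")])
        from edgemarker.features import CoexpressionWeights

        w = CoexpressionWeights(raw=np.array([raw]), network=net)
        assert threshold_coexpression(w, k).thresholded[0] == pytest.approx(expected)

    def test_idempotent_and_monotone_in_cutoff(self, rng):
        from edgemarker.features import CoexpressionWeights

        net = InteractionNetwork([(f"a{i}", f"b{i}") for i in range(50)])
        w = CoexpressionWeights(raw=rng.uniform(-1, 1, 50), network=net)
        prev_alive = None
        for k in (0.0, 0.25, 0.5, 0.75, 1.0):
            t1 = threshold_coexpression(w, k)
            t2 = threshold_coexpression(
                CoexpressionWeights(raw=t1.thresholded, network=net), k
            )
            np.testing.assert_array_equal(t1.thresholded, t2.thresholded)
            alive = set(np.flatnonzero(t1.thresholded))
            if prev_alive is not None:
                assert alive <= prev_alive  # raising k never resurrects an edge
            prev_alive = alive

    def test_absolute_mode_keeps_anticorrelated_magnitude(self):
        from edgemarker.features import CoexpressionWeights

        net = InteractionNetwork([("u", "v")])
        w = CoexpressionWeights(raw=np.array([-0.8]), network=net)
        assert threshold_coexpression(w, 0.5).thresholded[0] == 0.0
        assert threshold_coexpression(w, 0.5, absolute=True).thresholded[0] == 0.8


class TestAssemble:
    def _system(self, small_expr, small_net, cutoff=0.5):
        weights = spearman_coexpression(small_expr, small_net)
        weights = threshold_coexpression(weights, cutoff)
        aff = mass_action_affinity(small_expr, small_net)
        return aff, weights

    def test_shapes(self, small_expr, small_net):
        aff, weights = self._system(small_expr, small_net, cutoff=-1.0)
        system = assemble_features(aff, weights, small_expr)
        assert system.n_edges == small_net.n_edges
        assert system.n_nodes == small_expr.n_genes
        assert system.edge_affinity.shape == (6, small_net.n_edges)

    def test_all_edges_below_cutoff_gives_node_only_system(self, small_expr, small_net):
        aff, weights = self._system(small_expr, small_net, cutoff=1.1)
        system = assemble_features(aff, weights, small_expr)
        assert system.n_edges == 0 and system.n_nodes == 4

    def test_empty_node_list_gives_edge_only_system(self, small_expr, small_net):
        aff, weights = self._system(small_expr, small_net, cutoff=-1.0)
        system = assemble_features(aff, weights, small_expr, node_gene_list=[])
        assert system.n_nodes == 0 and system.n_edges == small_net.n_edges

    def test_unknown_node_gene_raises(self, small_expr, small_net):
        aff, weights = self._system(small_expr, small_net)
        with pytest.raises(ValidationError, match="gZ"):
            assemble_features(aff, weights, small_expr, node_gene_list=["gZ"])

    def test_dropping_zero_B_edges_preserves_lp_optimum(self, small_expr, small_net):
        """Edges with B = 0 contribute nothing: same optimum kept or dropped."""
        weights = spearman_coexpression(small_expr, small_net)
        aff = mass_action_affinity(small_expr, small_net)
        params = ModelParams(alpha=0.5, penalty_C=10.0)
        cut = threshold_coexpression(weights, 0.5)
        dropped = assemble_features(aff, cut, small_expr)

        # keep-everything variant: zero-B edges stay as all-zero columns
        kept = assemble_features(aff, cut, small_expr)
        kept.edge_pairs = list(small_net.edges)
        kept.edge_affinity = aff.values
        kept.edge_coexpression = np.where(
            cut.thresholded != 0, cut.thresholded, 0.0
        )
        kept.edge_src_idx = np.arange(small_net.n_edges)

        classes = class_centroids(aff, small_expr)
        sol_drop = solve_lp(build_lp(dropped, classes, params))
        sol_keep = solve_lp(build_lp(kept, classes, params))
        assert sol_drop.objective == pytest.approx(sol_keep.objective, abs=1e-9)
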