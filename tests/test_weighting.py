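"""AHP priorities, entropy weights, blending and hierarchy roll-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmindex.index_model import Indicator, IndicatorTree, NormalizationRule
from dmindex.weighting import (
    JudgmentMatrix,
    aggregate_experts,
    ahp_priority,
    build_weight_bundle,
    combine_weights,
    entropy_weights,
    global_ahp_weights,
    local_from_global,
    rollup_weights,
)

weight_vectors = st.lists(
    st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=7
).map(lambda v: np.asarray(v) / np.sum(v))


class TestAhpPriority:
    def test_two_by_two_closed_form(self):
        pv = ahp_priority(JudgmentMatrix(np.array([[1, 3], [1 / 3, 1]])))
        np.testing.assert_allclose(pv.weights, [0.75, 0.25], atol=1e-10)
        assert pv.lambda_max == pytest.approx(2.0)
        assert pv.cr == 0.0

    def test_all_ones_gives_uniform(self):
        pv = ahp_priority(JudgmentMatrix(np.ones((3, 3))))
        np.testing.assert_allclose(pv.weights, 1 / 3, atol=1e-10)
        assert pv.ci == pytest.approx(0.0, abs=1e-9)

    @given(weight_vectors)
    @settings(max_examples=40, deadline=None)
    def test_consistent_matrix_recovery(self, w):
        a = w[:, None] / w[None, :]
        pv = ahp_priority(JudgmentMatrix(a))
        np.testing.assert_allclose(pv.weights, w, atol=1e-8)
        assert pv.ci == pytest.approx(0.0, abs=1e-8)

    def test_matches_numpy_principal_eigenvector(self):
        rng = np.random.default_rng(3)
        w = rng.dirichlet(np.ones(5))
        eps = 0.3 * rng.standard_normal((5, 5))
        eps = np.triu(eps, 1) - np.triu(eps, 1).T
        a = (w[:, None] / w[None, :]) * np.exp(eps)
        pv = ahp_priority(JudgmentMatrix(a))
        vals, vecs = np.linalg.eig(a)
        lead = np.argmax(vals.real)
        ref = np.abs(vecs[:, lead].real)
        np.testing.assert_allclose(pv.weights, ref / ref.sum(), atol=1e-8)
        assert pv.lambda_max == pytest.approx(float(vals[lead].real), abs=1e-8)
        assert pv.cr > 0

    def test_non_reciprocal_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            JudgmentMatrix(np.array([[1.0, 2.0], [1.0, 1.0]]))


class TestAggregateExperts:
    def test_single_matrix_is_identity_operation(self):
        m = JudgmentMatrix(np.array([[1, 2], [0.5, 1]]))
        np.testing.assert_allclose(aggregate_experts([m]).a, m.a)

    def test_reciprocal_pair_cancels_to_ones(self):
        m = np.array([[1, 4], [0.25, 1]])
        agg = aggregate_experts([JudgmentMatrix(m), JudgmentMatrix(1 / m)])
        np.testing.assert_allclose(agg.a, 1.0)

    def test_geometric_mean_example(self):
        agg = aggregate_experts([
            JudgmentMatrix(np.array([[1, 2], [0.5, 1]])),
            JudgmentMatrix(np.array([[1, 8], [0.125, 1]])),
        ])
        np.testing.assert_allclose(agg.a, [[1, 4], [0.25, 1]])

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="same size"):
            aggregate_experts([JudgmentMatrix(np.ones((2, 2))), JudgmentMatrix(np.ones((3, 3)))])


def _two_domain_tree():
    return IndicatorTree([
        Indicator("1", "d1"), Indicator("1.1", "g1"),
        Indicator("1.1.1", "a", rule=NormalizationRule("binary")),
        Indicator("1.1.2", "b", rule=NormalizationRule("binary")),
        Indicator("2", "d2"), Indicator("2.1", "g2"),
        Indicator("2.1.1", "c", rule=NormalizationRule("binary")),
        Indicator("2.1.2", "d", rule=NormalizationRule("binary")),
    ])


class TestGlobalWeights:
    def test_products_along_paths(self):
        t = _two_domain_tree()
        local = {
            None: {"1": 0.6, "2": 0.4},
            "1": {"1.1": 1.0}, "2": {"2.1": 1.0},
            "1.1": {"1.1.1": 0.5, "1.1.2": 0.5},
            "2.1": {"2.1.1": 0.5, "2.1.2": 0.5},
        }
        g = global_ahp_weights(t, local)
        assert g == pytest.approx({"1.1.1": 0.3, "1.1.2": 0.3, "2.1.1": 0.2, "2.1.2": 0.2})

    def test_single_chain_leaf_gets_unit_weight(self):
        t = IndicatorTree([Indicator("1", "d"), Indicator("1.1", "g"),
                           Indicator("1.1.1", "leaf", rule=NormalizationRule("binary"))])
        g = global_ahp_weights(t, {None: {"1": 1.0}, "1": {"1.1": 1.0}, "1.1": {"1.1.1": 1.0}})
        assert g["1.1.1"] == pytest.approx(1.0)

    def test_missing_group_is_error(self):
        t = _two_domain_tree()
        with pytest.raises(ValueError, match="1.1"):
            global_ahp_weights(t, {None: {"1": 0.5, "2": 0.5}, "1": {"1.1": 1.0},
                                   "2": {"2.1": 1.0}, "2.1": {"2.1.1": 0.5, "2.1.2": 0.5}})

    def test_fixture_local_global_roundtrip(self, tree, bundle):
        # within-parent renormalization of leaf roll-ups, then synthesis,
        # reproduces the fixture's global AHP leaf weights
        leaf_w = {c: bundle.w_ahp[c] for c in tree.leaves}
        local = local_from_global(tree, rollup_weights(tree, leaf_w))
        g = global_ahp_weights(tree, local)
        leaf_sum = sum(leaf_w.values())
        for code, val in g.items():
            assert val == pytest.approx(leaf_w[code] / leaf_sum, abs=1e-6)


class TestEntropyWeights:
    def test_symmetric_hand_example(self):
        res = entropy_weights(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]), [0.5, 0.5])
        np.testing.assert_allclose(res.e, 0.6309, atol=5e-5)
        np.testing.assert_allclose(res.mu, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(res.theta, [0.5, 0.5], atol=1e-12)

    def test_constant_column_gets_zero_weight(self):
        res = entropy_weights(np.array([[1.0, 1.0], [3.0, 1.0]]), [0.5, 0.5])
        np.testing.assert_allclose(res.p[:, 0], [0.25, 0.75])
        assert res.e[0] == pytest.approx(0.8113, abs=5e-5)
        assert res.e[1] == pytest.approx(1.0)
        np.testing.assert_allclose(res.theta, [1.0, 0.0], atol=1e-12)

    def test_invariant_sums(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, size=(30, 6))
        w = rng.dirichlet(np.ones(6))
        res = entropy_weights(x, w)
        assert res.mu.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.theta.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((res.e >= 0) & (res.e <= 1))
        np.testing.assert_allclose(res.g, 1 - res.e)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 1, size=(20, 4))
        w = np.full(4, 0.25)
        res = entropy_weights(x, w)
        rows = rng.permutation(20)
        np.testing.assert_allclose(entropy_weights(x[rows], w).theta, res.theta)
        cols = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(entropy_weights(x[:, cols], w[cols]).theta, res.theta[cols])

    def test_added_dispersion_raises_relative_weight(self):
        rng = np.random.default_rng(9)
        base = 0.5 + 0.01 * rng.standard_normal((50, 3))
        spread = base.copy()
        spread[:, 0] = 0.5 + 0.4 * np.sign(rng.standard_normal(50))  # mean held at 0.5
        w = np.full(3, 1 / 3)
        t0 = entropy_weights(np.abs(base), w).theta
        t1 = entropy_weights(np.abs(spread), w).theta
        assert t1[0] > t0[0]

    def test_all_constant_matrix_is_error(self):
        with pytest.raises(ValueError, match="no discriminating information"):
            entropy_weights(np.ones((5, 3)), np.full(3, 1 / 3))


class TestCombineAndRollup:
    @pytest.mark.parametrize("w,theta,expected", [
        (0.0019, 0.0019, 0.0019),       # equal inputs are a fixed point for any rho
        (0.0555, 0.1151, 0.0853),
    ])
    def test_published_blends(self, w, theta, expected):
        out = combine_weights({"x": w}, {"x": theta}, rho=0.5)
        assert round(out["x"], 4) == pytest.approx(expected)

    def test_rho_limits_and_linearity(self):
        w, theta = {"a": 0.7, "b": 0.3}, {"a": 0.2, "b": 0.8}
        assert combine_weights(w, theta, rho=1.0) == pytest.approx(w)
        assert combine_weights(w, theta, rho=0.0) == pytest.approx(theta)
        mid = combine_weights(w, theta, rho=0.25)
        assert mid["a"] == pytest.approx(0.25 * 0.7 + 0.75 * 0.2)
        assert sum(mid.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="different indicators"):
            combine_weights({"a": 1.0}, {"b": 1.0})

    def test_fixture_domain_rollups(self, tree, bundle):
        blend = combine_weights(
            {c: bundle.w_ahp[c] for c in tree.leaves},
            {c: bundle.theta[c] for c in tree.leaves},
            rho=0.5,
        )
        rolled = rollup_weights(tree, blend)
        assert rolled["2"] == pytest.approx(0.1241, abs=2e-4)
        assert sum(rolled[d] for d in tree.domains) == pytest.approx(1.0, abs=5e-4)

    def test_single_leaf_rolls_to_one(self):
        t = IndicatorTree([Indicator("1", "d"), Indicator("1.1", "g"),
                           Indicator("1.1.1", "leaf", rule=NormalizationRule("binary"))])
        assert rollup_weights(t, {"1.1.1": 1.0})["1"] == 1.0

    def test_orphan_weight_rejected(self, tree):
        weights = {c: 1 / 56 for c in tree.leaves}
        weights["9.9.9"] = 0.1
        with pytest.raises(ValueError, match="9.9.9"):
            rollup_weights(tree, weights)

    def test_build_weight_bundle_consistency(self, tree, bundle):
        out = build_weight_bundle(
            tree,
            {c: bundle.w_ahp[c] for c in tree.leaves},
            {c: bundle.theta[c] for c in tree.leaves},
        )
        for node in tree.internal_nodes:
            assert out.w_combined[node] == pytest.approx(
                sum(out.w_combined[k] for k in tree.children(node)), abs=1e-12)
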