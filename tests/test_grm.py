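import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normforge.grm import (
    GRMParams,
    category_probs,
    cumulative_prob,
    default_grid,
    eap_sum_table,
    expected_item_given_total,
    fit_grm,
    item_fit_s_chi2,
    sumscore_likelihoods,
)
from normforge.simulate import ItemBank, simulate_responses


def brute_force_sum_likelihoods(params, grid):
    """Exhaustive enumeration over all response patterns (oracle)."""
    Ks = [bi.size + 1 for bi in params.b]
    L = np.zeros((sum(Ks) - len(Ks) + 1, grid.nodes.size))
    for pattern in itertools.product(*[range(k) for k in Ks]):
        p = np.ones(grid.nodes.size)
        for j, k in enumerate(pattern):
            p *= category_probs(params.a[j], params.b[j], grid.nodes)[:, k]
        L[sum(pattern)] += p
    return L


class TestProbabilities:
    def test_logistic_midpoint(self):
        assert cumulative_prob(1.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert cumulative_prob(2.0, -1.0, 0.0) == pytest.approx(0.8808, abs=1e-4)

    def test_extreme_trait_limit(self):
        assert cumulative_prob(1.0, 0.0, -50.0) < 1e-20

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            cumulative_prob(0.0, 0.0, 0.0)

    def test_three_category_hand_values(self):
        p = category_probs(2.0, np.array([-1.0, 1.0]), 0.0)
        assert p == pytest.approx([0.1192, 0.7616, 0.1192], abs=1e-4)

    def test_symmetric_thresholds_symmetric_tails(self):
        p = category_probs(1.3, np.array([-0.8, 0.8]), 0.0)
        assert p[0] == pytest.approx(p[-1])

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            category_probs(1.0, np.array([1.0, -1.0]), 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.2, 4.0),
        b1=st.floats(-3.0, 2.0),
        gap=st.floats(0.1, 2.0),
        theta=st.floats(-5.0, 5.0),
    )
    def test_probabilities_form_a_distribution(self, a, b1, gap, theta):
        p = category_probs(a, np.array([b1, b1 + gap, b1 + 2 * gap]), theta)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0)


class TestSumScoreLikelihoods:
    def test_single_item_base_case(self, grid):
        params = GRMParams(["i1"], [1.4], [np.array([-0.6, 0.9])])
        L = sumscore_likelihoods(params, grid)
        assert np.allclose(L.T, category_probs(1.4, np.array([-0.6, 0.9]), grid.nodes))

    def test_two_binary_items_at_zero(self, grid):
        params = GRMParams(["i1", "i2"], [1.0, 1.0], [np.array([0.0]), np.array([0.0])])
        L = sumscore_likelihoods(params, grid)
        mid = np.argmin(np.abs(grid.nodes))
        assert L[:, mid] == pytest.approx([0.25, 0.5, 0.25])

    def test_matches_exhaustive_enumeration(self, tiny_params, grid):
        L = sumscore_likelihoods(tiny_params, grid)
        oracle = brute_force_sum_likelihoods(tiny_params, grid)
        assert np.max(np.abs(L - oracle)) < 1e-12

    def test_partition_of_unity_at_every_node(self, tiny_params, grid):
        L = sumscore_likelihoods(tiny_params, grid)
        assert np.max(np.abs(L.sum(axis=0) - 1.0)) < 1e-12


class TestEAPSumTable:
    def test_symmetric_items_give_zero_at_middle(self, grid):
        params = GRMParams(["i1", "i2"], [1.0, 1.0], [np.array([0.0]), np.array([0.0])])
        t = eap_sum_table(params, grid)
        assert t.theta[1] == pytest.approx(0.0, abs=1e-12)

    def test_fine_grid_oracle(self, tiny_params):
        coarse = eap_sum_table(tiny_params, default_grid(61, 6.0))
        fine = eap_sum_table(tiny_params, default_grid(601, 6.0))
        assert np.max(np.abs(coarse.theta - fine.theta)) < 1e-4

    def test_strictly_increasing_in_score(self, tiny_params, grid):
        t = eap_sum_table(tiny_params, grid)
        assert np.all(np.diff(t.theta) > 0)
        assert np.all(t.se > 0)


class TestCalibration:
    def test_parameter_recovery_single_run(self, bank10, grid):
        traits = np.random.default_rng(42).standard_normal(2000)
        m = simulate_responses(bank10, traits, seed=7)
        res = fit_grm(m.responses, bank10.spec.items, grid)
        assert res.converged
        a_true, a_hat = bank10.params.a, res.params.a
        assert np.corrcoef(a_true, a_hat)[0, 1] >= 0.9
        b_true = np.concatenate(bank10.params.b)
        b_hat = np.concatenate(res.params.b)
        assert np.sqrt(np.mean((b_hat - b_true) ** 2)) <= 0.15

    def test_loglik_monotone_nondecreasing(self, bank10, grid):
        traits = np.random.default_rng(1).standard_normal(500)
        m = simulate_responses(bank10, traits, seed=2)
        res = fit_grm(m.responses, bank10.spec.items, grid)
        assert np.all(np.diff(res.loglik_path) > -1e-8)

    def test_constant_item_rejected(self, grid):
        X = np.column_stack([np.zeros(100, int), np.random.default_rng(0).integers(0, 3, 100)])
        with pytest.raises(ValueError, match="single observed category"):
            fit_grm(X, ["c", "v"], grid)

    def test_bit_reproducible(self, bank10, grid):
        traits = np.random.default_rng(3).standard_normal(400)
        m = simulate_responses(bank10, traits, seed=4)
        r1 = fit_grm(m.responses, bank10.spec.items, grid)
        r2 = fit_grm(m.responses, bank10.spec.items, grid)
        assert np.array_equal(r1.params.a, r2.params.a)
        assert all(np.array_equal(x, y) for x, y in zip(r1.params.b, r2.params.b))


class TestItemFit:
    def test_expected_frequencies_match_enumeration(self, tiny_params, grid):
        """Conditional category probabilities vs exhaustive pattern sums."""
        Ks = [bi.size + 1 for bi in tiny_params.b]
        S = sum(Ks) - len(Ks)
        w = grid.weights
        for j in range(3):
            cond = expected_item_given_total(tiny_params, grid, j)
            joint = np.zeros((S + 1, Ks[j]))
            for pattern in itertools.product(*[range(k) for k in Ks]):
                p = np.ones(grid.nodes.size)
                for i, k in enumerate(pattern):
                    p *= category_probs(tiny_params.a[i], tiny_params.b[i], grid.nodes)[:, k]
                joint[sum(pattern), pattern[j]] += float(p @ w)
            oracle = joint / joint.sum(axis=1, keepdims=True)
            assert np.max(np.abs(cond - oracle)) < 1e-10

    def test_null_data_not_flagged(self, bank10, grid):
        traits = np.random.default_rng(21).standard_normal(2000)
        m = simulate_responses(bank10, traits, seed=22)
        res = fit_grm(m.responses, bank10.spec.items, grid)
        fit = item_fit_s_chi2(m.responses, res.params, grid)
        assert fit.flagged.sum() == 0

    def test_injected_misfit_flagged(self, bank10, grid):
        shifted = [bi + (1.0 if j == 4 else 0.0) for j, bi in enumerate(bank10.params.b)]
        bad_bank = ItemBank(
            bank10.spec, GRMParams(list(bank10.spec.items), bank10.params.a, shifted)
        )
        m = simulate_responses(bad_bank, np.random.default_rng(31).standard_normal(2000), seed=32)
        fit = item_fit_s_chi2(m.responses, bank10.params, grid)
        assert fit.flagged[4]
        assert np.all(fit.statistic >= 0)
        assert np.all(fit.df >= 1)
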