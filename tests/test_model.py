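"""Unit and property tests for the CCM state space, rate matrix,
transition probabilities and pruning likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phyloccm as pc
from phyloccm.errors import (
    InvalidBranchLengthError,
    InvalidStateError,
    StateSpaceTooLargeError,
    TreeShapeError,
    MissingTipError,
)
from phyloccm.model import MAX_FEATURES

from conftest import enumeration_log_likelihood, random_pair_params


class TestStateIndex:
    @pytest.mark.parametrize(
        "state,expected",
        [((-1, -1), 0), ((1, 1), 3), ((1, -1), 1), ((-1, 1), 2), ((-1,), 0)],
    )
    def test_bit_convention(self, state, expected):
        assert pc.state_index(state) == expected

    def test_bijective_over_full_space(self):
        X = pc.state_space(3)
        assert sorted(pc.state_index(row) for row in X) == list(range(8))
        assert np.array_equal(X[5], [1, -1, 1])  # index 5 = bits 101

    def test_rejects_non_sign_entries(self):
        with pytest.raises(InvalidStateError):
            pc.state_index((0, 1))


class TestTransitionRate:
    def test_neutral_parameters_give_unit_rate(self):
        p = pc.CCMParameters((0.0,), (0.0,))
        assert pc.transition_rate((-1,), 0, p) == pytest.approx(1.0)

    def test_gain_loss_asymmetry(self):
        # beta_kk is half the gain/loss log-rate difference: gain = e^(a+b),
        # loss = e^(a-b).
        c = 0.7
        p = pc.CCMParameters((0.0,), (c,))
        assert pc.transition_rate((-1,), 0, p) == pytest.approx(np.exp(c))
        assert pc.transition_rate((1,), 0, p) == pytest.approx(np.exp(-c))

    def test_interaction_suppresses_loss_of_copresent_partner(self):
        b = 1.3
        p = pc.CCMParameters.for_pair(0, 0, 0, 0, b)
        assert pc.transition_rate((1, 1), 0, p) == pytest.approx(np.exp(-b))
        # and accelerates the partner's gain when the other is present
        assert pc.transition_rate((-1, 1), 0, p) == pytest.approx(np.exp(b))


class TestRateMatrix:
    def test_single_feature_unit_rates(self):
        Q = pc.build_rate_matrix(pc.CCMParameters((0.0,), (0.0,)))
        assert np.allclose(Q, [[-1, 1], [1, -1]])

    def test_two_features_all_zero(self):
        Q = pc.build_rate_matrix(pc.CCMParameters.for_pair(0, 0, 0, 0, 0))
        off = Q - np.diag(np.diag(Q))
        assert np.allclose(np.diag(Q), -2)
        for i in range(4):
            for j in range(4):
                expected = 1.0 if bin(i ^ j).count("1") == 1 else 0.0
                if i != j:
                    assert off[i, j] == pytest.approx(expected)

    def test_strong_positive_interaction_freezes_copresence(self):
        rate_out = []
        for b in (1.0, 5.0, 20.0):
            Q = pc.build_rate_matrix(pc.CCMParameters.for_pair(0, 0, 0, 0, b))
            rate_out.append(-Q[3, 3])  # total rate of leaving (+1,+1)
        assert rate_out[0] > rate_out[1] > rate_out[2]
        assert rate_out[2] == pytest.approx(0.0, abs=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_generator_contracts(self, seed, n):
        """Rows sum to zero, off-diagonals nonnegative, single-flip sparsity."""
        rng = np.random.default_rng(seed)
        n_pairs = n * (n - 1) // 2
        p = pc.CCMParameters(
            tuple(rng.normal(0, 1, n)),
            tuple(rng.normal(0, 1, n)),
            tuple(rng.normal(0, 1, n_pairs)),
        )
        Q = pc.build_rate_matrix(p)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        for i in range(2**n):
            for j in range(2**n):
                if i == j:
                    continue
                assert Q[i, j] >= 0
                if bin(i ^ j).count("1") != 1:
                    assert Q[i, j] == 0

    def test_state_space_guard(self):
        n = MAX_FEATURES + 1
        p = pc.CCMParameters(
            (0.0,) * n, (0.0,) * n, (0.0,) * (n * (n - 1) // 2)
        )
        with pytest.raises(StateSpaceTooLargeError):
            pc.build_rate_matrix(p)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = pc.build_rate_matrix(pc.CCMParameters.for_pair(1, -1, 0.5, 0, 2))
        assert np.array_equal(pc.transition_probabilities(Q, 0.0), np.eye(4))

    def test_negative_time_rejected(self):
        Q = pc.build_rate_matrix(pc.CCMParameters((0.0,), (0.0,)))
        with pytest.raises(InvalidBranchLengthError):
            pc.transition_probabilities(Q, -0.1)

    @pytest.mark.parametrize("t", [0.01, 0.5, 2.0, 10.0])
    def test_symmetric_two_state_closed_form(self, t):
        """Equal gain/loss rates: P(stay) = (1 + e^{-2t}) / 2."""
        Q = pc.build_rate_matrix(pc.CCMParameters((0.0,), (0.0,)))
        P = pc.transition_probabilities(Q, t)
        stay = (1 + np.exp(-2 * t)) / 2
        assert np.allclose(np.diag(P), stay, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_stochastic_and_chapman_kolmogorov(self, seed):
        rng = np.random.default_rng(seed)
        p = random_pair_params(rng)
        Q = pc.build_rate_matrix(p)
        s, t = rng.uniform(0, 50, 2)
        Ps, Pt, Pst = (
            pc.transition_probabilities(Q, x) for x in (s, t, s + t)
        )
        for P in (Ps, Pt, Pst):
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
            assert P.min() >= 0
        assert np.allclose(Ps @ Pt, Pst, atol=1e-8)

    def test_stack_matches_single_branch_exponentials(self, rng):
        p = random_pair_params(rng)
        Q = pc.build_rate_matrix(p)
        ts = np.array([0.0, 0.1, 1.0, 7.5])
        stack = pc.transition_stack(Q, ts)
        for P, t in zip(stack, ts):
            assert np.allclose(P, pc.transition_probabilities(Q, t), atol=1e-9)


class TestPruningLikelihood:
    def test_matches_enumeration_on_small_trees(
        self, rng, three_leaf_tree, four_leaf_tree
    ):
        """Pruning equals the explicit sum over internal-state assignments."""
        tips3 = {"A": (1, -1), "B": (-1, -1), "C": (1, 1)}
        tips4 = {"A": (1, 1), "B": (-1, 1), "C": (1, -1), "D": (-1, -1)}
        for _ in range(20):
            p = random_pair_params(rng)
            for tree, tips in ((three_leaf_tree, tips3), (four_leaf_tree, tips4)):
                got = pc.tree_log_likelihood(tree, tips, p)
                want = enumeration_log_likelihood(tree, tips, p)
                assert got == pytest.approx(want, abs=1e-8)

    def test_single_feature_matches_enumeration(self, rng, three_leaf_tree):
        tips = {"A": (1,), "B": (-1,), "C": (1,)}
        for _ in range(10):
            a, b = rng.normal(0, 1, 2)
            p = pc.CCMParameters((a,), (b,))
            got = pc.tree_log_likelihood(three_leaf_tree, tips, p)
            want = enumeration_log_likelihood(three_leaf_tree, tips, p)
            assert got == pytest.approx(want, abs=1e-8)

    def test_independent_features_factorize(self, rng, four_leaf_tree):
        """With beta_12 = 0 the joint log-likelihood is the sum of the two
        single-feature log-likelihoods (uniform root factorizes)."""
        tips = {"A": (1, 1), "B": (-1, 1), "C": (1, -1), "D": (-1, -1)}
        for _ in range(10):
            a1, a2, b1, b2 = rng.normal(0, 1, 4)
            joint = pc.tree_log_likelihood(
                four_leaf_tree, tips, pc.CCMParameters.for_pair(a1, a2, b1, b2, 0.0)
            )
            ll1 = pc.tree_log_likelihood(
                four_leaf_tree,
                {k: (v[0],) for k, v in tips.items()},
                pc.CCMParameters((a1,), (b1,)),
            )
            ll2 = pc.tree_log_likelihood(
                four_leaf_tree,
                {k: (v[1],) for k, v in tips.items()},
                pc.CCMParameters((a2,), (b2,)),
            )
            assert joint == pytest.approx(ll1 + ll2, abs=1e-8)

    def test_invariant_to_leaf_enumeration_order(self, rng):
        p = random_pair_params(rng)
        tips = {"A": (1, -1), "B": (-1, -1), "C": (1, 1)}
        t1 = pc.read_newick("(A:0.4,(B:0.3,C:0.7):0.2);")
        t2 = pc.read_newick("((C:0.7,B:0.3):0.2,A:0.4);")
        assert pc.tree_log_likelihood(t1, tips, p) == pytest.approx(
            pc.tree_log_likelihood(t2, tips, p), abs=1e-10
        )

    def test_invariant_to_feature_relabeling(self, rng, four_leaf_tree):
        p = random_pair_params(rng)
        swapped = pc.CCMParameters.for_pair(
            p.alpha[1], p.alpha[0], p.beta_diag[1], p.beta_diag[0], p.beta_inter[0]
        )
        tips = {"A": (1, 1), "B": (-1, 1), "C": (1, -1), "D": (-1, -1)}
        tips_sw = {k: (v[1], v[0]) for k, v in tips.items()}
        assert pc.tree_log_likelihood(four_leaf_tree, tips, p) == pytest.approx(
            pc.tree_log_likelihood(four_leaf_tree, tips_sw, swapped), abs=1e-10
        )

    def test_zero_length_tree_concentrates_on_root_distribution(self):
        tree = pc.read_newick("(A:0.0,B:0.0);")
        p = pc.CCMParameters((0.3,), (0.1,))
        ll = pc.tree_log_likelihood(tree, {"A": (1,), "B": (1,)}, p)
        # identity transitions: both tips equal the root state, mass 1/2
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_missing_tip_and_nonbinary_errors(self, three_leaf_tree):
        p = random_pair_params(np.random.default_rng(0))
        with pytest.raises(MissingTipError):
            pc.tree_log_likelihood(three_leaf_tree, {"A": (1, 1)}, p)
        poly = pc.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeShapeError):
            pc.tree_log_likelihood(
                poly, {"A": (1, 1), "B": (1, 1), "C": (1, 1)}, p
            )
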