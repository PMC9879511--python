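"""Encoder correctness: brute-force oracle equivalence, invariants, locality."""

import numpy as np
import pytest

from ddisub.autodiff import Var
from ddisub.dmpnn import (EncoderParams, aggregate_bond_states,
                          compute_bond_importance, encode, init_bond_states,
                          message_step, substructure_attention,
                          update_bond_states)
from ddisub.molgraph import ATOM_FDIM, BOND_FDIM, parse_smiles, permute_graph

from conftest import path_graph, random_path_graph
from oracle import dense_encode


def small_params(rng, hidden=5, T=2, in_dim=ATOM_FDIM, **kw):
    return EncoderParams.create(rng, hidden=hidden, T=T, in_dim=in_dim, **kw)


class TestInitBondStates:
    def test_zero_weights_give_zero_states(self, rng):
        g = parse_smiles("CCO")
        p = small_params(rng)
        for w in (p.W_i, p.W_j, p.W_ij):
            w.data[:] = 0.0
        assert np.all(init_bond_states(g, p).data == 0.0)

    def test_identity_atom_weights_sum_endpoint_features(self, rng):
        g = parse_smiles("CCO")
        p = small_params(rng, hidden=ATOM_FDIM)
        p.W_i.data = np.eye(ATOM_FDIM)
        p.W_j.data = np.eye(ATOM_FDIM)
        p.W_ij.data[:] = 0.0
        h0 = init_bond_states(g, p).data
        for k in range(g.n_directed_bonds):
            np.testing.assert_allclose(
                h0[k], g.atom_features[g.bond_src[k]] + g.atom_features[g.bond_dst[k]])

    def test_shape_mismatch_raises(self, rng):
        g = parse_smiles("CC")
        p = small_params(rng, in_dim=10)
        with pytest.raises(ValueError, match="dim"):
            init_bond_states(g, p)


class TestBondImportance:
    def test_single_incoming_bond_gets_weight_one(self, rng):
        g = parse_smiles("CC")  # each atom has exactly one incoming bond
        p = small_params(rng)
        beta = compute_bond_importance(g, init_bond_states(g, p), p)
        np.testing.assert_allclose(beta.data, [1.0, 1.0], atol=1e-12)

    def test_symmetric_incoming_bonds_split_evenly(self):
        # path A-B-C with identical atom/bond features everywhere: the two
        # bonds into B are indistinguishable
        x = np.tile(np.eye(ATOM_FDIM)[1], (3, 1))
        g = path_graph(x)
        p = small_params(np.random.default_rng(3))
        beta = compute_bond_importance(g, init_bond_states(g, p), p)
        into_b = beta.data[np.asarray(g.bond_dst) == 1]
        np.testing.assert_allclose(into_b, [0.5, 0.5], atol=1e-12)

    def test_matches_dense_softmax_oracle(self, rng):
        g = random_path_graph(rng, 4)
        p = small_params(rng)
        states = init_bond_states(g, p)
        beta = compute_bond_importance(g, states, p)
        from oracle import dense_beta

        np.testing.assert_allclose(beta.data, dense_beta(g, states.data, p),
                                   atol=1e-10)


class TestMessageStep:
    def test_two_atom_graph_update_reduces_to_relu_of_init(self, rng):
        # the only incoming bond at each source is the reverse bond, which
        # is excluded, so the neighborhood sum is empty
        g = parse_smiles("CO")
        p = small_params(rng)
        h0 = init_bond_states(g, p)
        h1 = update_bond_states(g, h0, h0, p)
        h2 = update_bond_states(g, h1, h0, p)
        np.testing.assert_allclose(h1.data, np.maximum(h0.data, 0.0), atol=1e-12)
        np.testing.assert_allclose(h2.data, h1.data, atol=1e-12)

    def test_single_atom_graph_messages_are_zero(self, rng):
        g = parse_smiles("C")
        p = small_params(rng)
        feats, trace = encode(g, p, return_trace=True)
        for m, gs in zip(trace.m_node, trace.g_step):
            assert np.all(m.data == 0.0)
            assert np.all(gs.data == 0.0)


class TestStepAttention:
    def test_single_step_attention_is_one(self, rng):
        g = parse_smiles("CCO")
        p = small_params(rng, T=1)
        _, trace = encode(g, p, return_trace=True)
        np.testing.assert_allclose(trace.alpha.data, [1.0], atol=1e-12)

    def test_equal_logits_give_uniform_attention(self, rng):
        p = small_params(rng, T=3)
        p.w_step.data[:] = 0.0  # all e^(t) = 0
        g = parse_smiles("CCCC")
        _, trace = encode(g, p, return_trace=True)
        np.testing.assert_allclose(trace.alpha.data, np.ones(3) / 3, atol=1e-12)

    def test_softmax_of_known_logits(self, rng):
        # craft parameters so e = (0, ln 3) -> alpha = (0.25, 0.75)
        h = 5
        p = small_params(rng, hidden=h, T=2)
        p.W_att.data[:] = 0.0
        p.b_att.data[:] = 1.0  # tanh(1) in every slot
        p.w_step.data[0, :] = 0.0
        p.w_step.data[1, :] = np.log(3.0) / (h * np.tanh(1.0))
        e, alpha = substructure_attention(
            [Var(np.zeros(h)), Var(np.zeros(h))], p)
        np.testing.assert_allclose(e.data, [0.0, np.log(3.0)], atol=1e-12)
        np.testing.assert_allclose(alpha.data, [0.25, 0.75], atol=1e-12)


class TestAggregation:
    def test_one_hot_alpha_selects_single_step(self, rng):
        states = [Var(rng.normal(size=(4, 3))) for _ in range(3)]
        out = aggregate_bond_states(states, Var(np.array([0.0, 1.0, 0.0])))
        np.testing.assert_allclose(out.data, states[1].data)

    def test_opposite_states_cancel(self, rng):
        v = rng.normal(size=(4, 3))
        out = aggregate_bond_states([Var(v), Var(-v)], Var(np.array([0.5, 0.5])))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


class TestOracleEquivalence:
    """Every intermediate matches the independent dense implementation."""

    @pytest.mark.parametrize("smiles", ["CC", "CCO", "C=CC", "CC(C)O", "C1CC1"])
    @pytest.mark.parametrize("recompute_beta", [True, False])
    def test_all_intermediates_on_small_molecules(self, smiles, recompute_beta):
        rng = np.random.default_rng(hash(smiles) % 2**31)
        g = parse_smiles(smiles)
        p = small_params(rng, hidden=6, T=3, recompute_beta=recompute_beta)
        feats, trace = encode(g, p, return_trace=True)
        ref = dense_encode(g, p)
        for t in range(p.T + 1):
            np.testing.assert_allclose(trace.bond_states[t].data,
                                       ref["bond_states"][t], atol=1e-6)
        for t in range(p.T):
            np.testing.assert_allclose(trace.beta[t].data, ref["beta"][t], atol=1e-6)
            np.testing.assert_allclose(trace.m_node[t].data, ref["m_node"][t], atol=1e-6)
            np.testing.assert_allclose(trace.g_step[t].data, ref["g_step"][t], atol=1e-6)
        np.testing.assert_allclose(trace.e_step.data, ref["e_step"], atol=1e-6)
        np.testing.assert_allclose(trace.alpha.data, ref["alpha"], atol=1e-6)
        np.testing.assert_allclose(trace.final_bond.data, ref["final_bond"], atol=1e-6)
        np.testing.assert_allclose(feats.data, ref["node_features"], atol=1e-6)


class TestEncodeProperties:
    def test_attention_normalization_over_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            g = random_path_graph(rng, n)
            p = small_params(rng, T=int(rng.integers(1, 4)))
            _, trace = encode(g, p, return_trace=True)
            assert abs(trace.alpha.data.sum() - 1.0) < 1e-6
            assert np.all(trace.alpha.data > 0.0)
            for beta in trace.beta:
                sums = np.zeros(g.n_atoms)
                np.add.at(sums, g.bond_dst, beta.data)
                np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_permutation_equivariance_of_node_features(self, rng):
        g = parse_smiles("NC(=O)c1ccc(Cl)cc1O")
        p = small_params(rng, hidden=8, T=2)
        feats = encode(g, p).data
        for _ in range(5):
            perm = rng.permutation(g.n_atoms)
            pf = encode(permute_graph(g, perm), p).data
            np.testing.assert_allclose(pf[perm], feats, rtol=1e-5, atol=1e-8)

    def test_bond_state_locality_on_a_chain(self, rng):
        # with frozen (compute-once) beta the step-t state of a bond can only
        # depend on bonds within t-1 line-graph hops; mutate the far end of
        # an 8-atom chain and check near-end bond states are unchanged
        n = 8
        x1 = rng.normal(size=(n, ATOM_FDIM))
        x2 = x1.copy()
        x2[n - 1] += 1.0  # mutate the terminal atom
        p = small_params(rng, T=2)
        g1, g2 = path_graph(x1), path_graph(x2)
        h0_1 = init_bond_states(g1, p)
        h0_2 = init_bond_states(g2, p)
        s1 = update_bond_states(g1, h0_1, h0_1, p)
        s2 = update_bond_states(g2, h0_2, h0_2, p)
        s1 = update_bond_states(g1, s1, h0_1, p)
        s2 = update_bond_states(g2, s2, h0_2, p)
        # bond 0 (atom0->atom1) is 5+ hops from the mutated terminal bonds
        np.testing.assert_allclose(s1.data[0], s2.data[0], atol=1e-10)
        # the last bond pair differs
        assert not np.allclose(s1.data[-1], s2.data[-1])
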