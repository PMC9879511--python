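"""Independent dense brute-force re-implementation of the encoder math.

Everything here is written with explicit Python loops over atoms and bonds
and plain NumPy arrays — no autodiff, no segment operations — so it shares
no code path with the package implementation it cross-checks.
"""

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def dense_init_bond_states(graph, params, x=None):
    x = graph.atom_features if x is None else x
    Wi, Wj, Wij = params.W_i.data, params.W_j.data, params.W_ij.data
    h0 = np.zeros((graph.n_directed_bonds, Wi.shape[0]))
    for k in range(graph.n_directed_bonds):
        i, j = graph.bond_src[k], graph.bond_dst[k]
        h0[k] = Wi @ x[i] + Wj @ x[j] + Wij @ graph.bond_features[k]
    return h0


def dense_update(graph, states, h0, params):
    Wm = params.W_m.data
    out = np.zeros_like(states)
    for k in range(graph.n_directed_bonds):
        i, j = graph.bond_src[k], graph.bond_dst[k]
        neigh = np.zeros(states.shape[1])
        for k2 in range(graph.n_directed_bonds):
            # bonds k2 -> i whose source is not j (exclude the reverse bond)
            if graph.bond_dst[k2] == i and graph.bond_src[k2] != j:
                neigh += states[k2]
        out[k] = relu(h0[k] + Wm @ neigh)
    return out


def dense_beta(graph, states, params):
    w = params.w_bond.data
    nb = graph.n_directed_bonds
    raw = np.zeros(nb)
    for k in range(nb):
        ends_k = {graph.bond_src[k], graph.bond_dst[k]}
        agg = states[k].copy()  # self-loop
        for k2 in range(nb):
            if k2 == k:
                continue
            ends_k2 = {graph.bond_src[k2], graph.bond_dst[k2]}
            if ends_k & ends_k2:
                agg += states[k2]
        raw[k] = w @ agg
    beta = np.zeros(nb)
    for i in range(graph.n_atoms):
        incoming = [k for k in range(nb) if graph.bond_dst[k] == i]
        if not incoming:
            continue
        e = np.exp(raw[incoming] - max(raw[k] for k in incoming))
        for k, ek in zip(incoming, e):
            beta[k] = ek / e.sum()
    return beta


def dense_node_messages(graph, states, beta):
    h = states.shape[1]
    m = np.zeros((graph.n_atoms, h))
    for k in range(graph.n_directed_bonds):
        m[graph.bond_dst[k]] += beta[k] * states[k]
    return m, m.sum(axis=0)


def dense_step_attention(g_steps, params):
    W, b = params.W_att.data, params.b_att.data
    e = np.array([params.w_step.data[t] @ np.tanh(W @ g + b)
                  for t, g in enumerate(g_steps)])
    ex = np.exp(e - e.max())
    return e, ex / ex.sum()


def dense_encode(graph, params, x=None):
    """Full dense forward pass; returns every intermediate by name."""
    x = graph.atom_features if x is None else x
    h0 = dense_init_bond_states(graph, params, x)
    states = h0
    bond_states, betas, m_nodes, g_steps = [h0], [], [], []
    beta = None if params.recompute_beta else dense_beta(graph, h0, params)
    for _t in range(params.T):
        states = dense_update(graph, states, h0, params)
        if params.recompute_beta:
            beta = dense_beta(graph, states, params)
        m, g = dense_node_messages(graph, states, beta)
        bond_states.append(states)
        betas.append(beta)
        m_nodes.append(m)
        g_steps.append(g)
    e, alpha = dense_step_attention(g_steps, params)
    final_bond = sum(a * s for a, s in zip(alpha, bond_states[1:]))
    W0 = params.W_0.data
    W1, b1 = params.mlp_W1.data, params.mlp_b1.data
    W2, b2 = params.mlp_W2.data, params.mlp_b2.data
    nodes = np.zeros((graph.n_atoms, W2.shape[0]))
    for i in range(graph.n_atoms):
        agg = W0 @ x[i]
        for k in range(graph.n_directed_bonds):
            if graph.bond_dst[k] == i:
                agg += final_bond[k]
        nodes[i] = W2 @ relu(W1 @ agg + b1) + b2
    return {
        "bond_states": bond_states,
        "beta": betas,
        "m_node": m_nodes,
        "g_step": g_steps,
        "e_step": e,
        "alpha": alpha,
        "final_bond": final_bond,
        "node_features": nodes,
    }
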