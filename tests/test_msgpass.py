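"""Typed message passing: per-node oracle, vectorized layer, equivariance."""

import numpy as np
import pandas as pd
import pytest

from synergraph.autodiff import Linear, Tensor
from synergraph.io import HeteroGraph, build_heterograph
from synergraph.msgpass import (MsgParams, NodeStates, aggregate_drug,
                                aggregate_protein, init_msg_params, mp_layer,
                                mp_layer_reference, update_node)

D = 6


def random_graph(rng, n_d, n_p, p_dti=0.4, p_ppi=0.3):
    dti = [(i, j) for i in range(n_d) for j in range(n_p) if rng.random() < p_dti]
    ppi = [(i, j) for i in range(n_p) for j in range(i + 1, n_p)
           if rng.random() < p_ppi]
    drugs = pd.DataFrame({"id": [f"d{i}" for i in range(n_d)], "smiles": "C"})
    prots = pd.DataFrame({"id": [f"p{i}" for i in range(n_p)], "sequence": "MK"})
    return build_heterograph(drugs, prots, dti, ppi, edge_dim=D,
                             seed=int(rng.integers(1 << 30)))


def identity_linear(d):
    return Linear(d, d, init="identity")


# -- per-node operations ------------------------------------------------


def test_empty_neighborhood_gives_zero_message():
    msg = aggregate_drug([], np.ones(D), identity_linear(D))
    np.testing.assert_array_equal(msg, np.zeros(D))


def test_single_neighbor_identity_projection_passes_state_through():
    h_j = np.arange(float(D))
    msg = aggregate_drug([h_j], np.ones(D), identity_linear(D))
    np.testing.assert_array_equal(msg, h_j)


def test_two_neighbors_sum_elementwise(rng):
    f = Linear(D, D, rng)
    e = rng.normal(size=D)
    h1, h2 = rng.normal(size=D), rng.normal(size=D)
    both = aggregate_drug([h1, h2], e, f)
    single = aggregate_drug([h1], e, f) + aggregate_drug([h2], e, f)
    np.testing.assert_allclose(both, single, rtol=1e-12)


def test_protein_message_splits_into_drug_and_protein_terms(rng):
    f_pd, f_pp = Linear(D, D, rng), Linear(D, D, rng)
    e1, e2 = rng.normal(size=D), rng.normal(size=D)
    hd, hp = [rng.normal(size=D)], [rng.normal(size=D), rng.normal(size=D)]
    mixed = aggregate_protein(hd, hp, e1, e2, f_pd, f_pp)
    drug_term = aggregate_protein(hd, [], e1, e2, f_pd, f_pp)
    prot_term = aggregate_protein([], hp, e1, e2, f_pd, f_pp)
    np.testing.assert_allclose(mixed, drug_term + prot_term, rtol=1e-12)


def test_update_is_message_plus_selfloop():
    h = np.array([1.0, -2.0, 3.0])
    assert np.array_equal(update_node(h, np.zeros(3), identity_linear(3)), h)
    m = np.array([0.5, 0.5, 0.5])
    np.testing.assert_allclose(update_node(h, m, identity_linear(3)), h + m)


# -- full layer ---------------------------------------------------------


def states_for(graph, rng):
    return NodeStates(Tensor(rng.normal(size=(graph.n_drugs, D))),
                      Tensor(rng.normal(size=(graph.n_proteins, D))))


def test_vectorized_layer_matches_naive_loop_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        g = random_graph(rng, int(rng.integers(2, 8)), int(rng.integers(2, 12)))
        params = init_msg_params(D, g, rng)
        st = states_for(g, rng)
        fast = mp_layer(g, st, params)
        ref_d, ref_p = mp_layer_reference(g, st.H_drug.data, st.H_prot.data, params)
        np.testing.assert_allclose(fast.H_drug.data, ref_d, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(fast.H_prot.data, ref_p, rtol=1e-6, atol=1e-9)


def test_zero_edge_graph_applies_selfloop_only(rng):
    drugs = pd.DataFrame({"id": ["d0", "d1"], "smiles": "C"})
    prots = pd.DataFrame({"id": ["p0", "p1"], "sequence": "MK"})
    g = build_heterograph(drugs, prots, [], [], edge_dim=D, seed=0)
    params = init_msg_params(D, g, rng)
    st = states_for(g, rng)
    out = mp_layer(g, st, params)
    np.testing.assert_allclose(out.H_drug.data, st.H_drug.data, rtol=1e-12)
    np.testing.assert_allclose(out.H_prot.data, st.H_prot.data, rtol=1e-12)


def test_no_ppi_reduces_protein_message_to_drug_term(rng):
    g = random_graph(rng, 3, 5, p_ppi=0.0)
    assert g.ppi_edges == []
    params = init_msg_params(D, g, rng)
    st = states_for(g, rng)
    out = mp_layer(g, st, params)
    ref_d, ref_p = mp_layer_reference(g, st.H_drug.data, st.H_prot.data, params)
    np.testing.assert_allclose(out.H_prot.data, ref_p, rtol=1e-6)


def test_permutation_equivariance():
    """Relabeling nodes and permuting inputs permutes outputs identically."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        g = random_graph(rng, 4, 6)
        params = init_msg_params(D, g, rng)
        st = states_for(g, rng)
        out = mp_layer(g, st, params)
        pd_ = rng.permutation(g.n_drugs)
        pp_ = rng.permutation(g.n_proteins)
        inv_d = np.argsort(pd_)
        inv_p = np.argsort(pp_)
        g2 = HeteroGraph(drug_ids=[g.drug_ids[i] for i in pd_],
                         protein_ids=[g.protein_ids[i] for i in pp_],
                         dti_edges=[(int(inv_d[a]), int(inv_p[b])) for a, b in g.dti_edges],
                         ppi_edges=[(int(inv_p[a]), int(inv_p[b])) for a, b in g.ppi_edges],
                         edge_feat=g.edge_feat)
        st2 = NodeStates(Tensor(st.H_drug.data[pd_]), Tensor(st.H_prot.data[pp_]))
        out2 = mp_layer(g2, st2, params)
        np.testing.assert_allclose(out2.H_drug.data, out.H_drug.data[pd_], rtol=1e-9)
        np.testing.assert_allclose(out2.H_prot.data, out.H_prot.data[pp_], rtol=1e-9)


def test_locality_perturbation_affects_only_neighbors():
    """Changing one protein's state changes itself and its neighbors only."""
    rng = np.random.default_rng(13)
    g = random_graph(rng, 4, 8, p_dti=0.25, p_ppi=0.2)
    params = init_msg_params(D, g, rng)
    st = states_for(g, rng)
    base = mp_layer(g, st, params)
    j = 3
    H_p2 = st.H_prot.data.copy()
    H_p2[j] += 1.0
    out = mp_layer(g, NodeStates(st.H_drug, Tensor(H_p2)), params)
    drug_nb = {d for d, p in g.dti_edges if p == j}
    prot_nb = {j} | {b for a, b in g.ppi_edges if a == j} | {a for a, b in g.ppi_edges if b == j}
    for i in range(g.n_drugs):
        changed = not np.allclose(out.H_drug.data[i], base.H_drug.data[i])
        assert changed == (i in drug_nb)
    for p in range(g.n_proteins):
        changed = not np.allclose(out.H_prot.data[p], base.H_prot.data[p])
        assert changed == (p in prot_nb)


def test_layer_rejects_mismatched_hidden_dims(rng):
    st = NodeStates(Tensor(np.zeros((2, 4))), Tensor(np.zeros((3, 5))))
    with pytest.raises(ValueError):
        st.validate()
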