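"""Shared helpers for building and relabeling small random heterogeneous graphs."""

import numpy as np
import pandas as pd

from synergraph.autodiff import Tensor
from synergraph.io import HeteroGraph, build_heterograph
from synergraph.msgpass import NodeStates


def random_small_graph(rng, max_nodes=20, p_dti=0.35, p_ppi=0.25):
    n_d = int(rng.integers(2, max(3, max_nodes // 3)))
    n_p = int(rng.integers(2, max(3, max_nodes - n_d)))
    dti = [(i, j) for i in range(n_d) for j in range(n_p) if rng.random() < p_dti]
    ppi = [(i, j) for i in range(n_p) for j in range(i + 1, n_p)
           if rng.random() < p_ppi]
    drugs = pd.DataFrame({"id": [f"d{i}" for i in range(n_d)], "smiles": "C"})
    prots = pd.DataFrame({"id": [f"p{i}" for i in range(n_p)], "sequence": "MK"})
    return build_heterograph(drugs, prots, dti, ppi, edge_dim=8,
                             seed=int(rng.integers(1 << 30)))


def permute_graph(rng, g, states):
    """Relabel nodes with random permutations; returns the permuted graph,
    permuted states and the permutations used."""
    pd_ = rng.permutation(g.n_drugs)
    pp_ = rng.permutation(g.n_proteins)
    inv_d, inv_p = np.argsort(pd_), np.argsort(pp_)
    g2 = HeteroGraph(
        drug_ids=[g.drug_ids[i] for i in pd_],
        protein_ids=[g.protein_ids[i] for i in pp_],
        dti_edges=[(int(inv_d[a]), int(inv_p[b])) for a, b in g.dti_edges],
        ppi_edges=[(int(inv_p[a]), int(inv_p[b])) for a, b in g.ppi_edges],
        edge_feat=g.edge_feat,
    )
    st2 = NodeStates(Tensor(states.H_drug.data[pd_]), Tensor(states.H_prot.data[pp_]))
    return g2, st2, pd_, pp_
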