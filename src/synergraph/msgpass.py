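"""Typed message passing on the heterogeneous drug-protein graph.

Each layer aggregates, for every node, edge-gated linear projections of
its neighbours' previous-layer states and adds a self-loop map of its own
previous state:

    drug i:     h_i^l = sum_{j in N_dti(i)} e_dti * f_dp(h_j^{l-1}) + eps_d(h_i^{l-1})
    protein j:  h_j^l = sum_{i in N_dti(j)} e_dti * f_pd(h_i^{l-1})
                      + sum_{k in N_ppi(j)} e_ppi * f_pp(h_k^{l-1}) + eps_p(h_j^{l-1})

where * is the elementwise product with the shared edge-type feature
vector, f_* are learned linear maps (one per edge direction) and the
self-loop maps eps_* are initialized to the identity so an isolated node
starts as a fixed point. Updates are synchronous: every layer-l state is
computed from layer-(l-1) states only.

`mp_layer` is the vectorized implementation used in training;
`aggregate_drug` / `aggregate_protein` / `update_node` are the per-node
reference forms, and `mp_layer_reference` loops them over the whole graph
as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Tensor
from .io import HeteroGraph

__all__ = [
    "NodeStates",
    "MsgParams",
    "init_msg_params",
    "aggregate_drug",
    "aggregate_protein",
    "update_node",
    "mp_layer",
    "mp_layer_reference",
]


@dataclass
class NodeStates:
    """Hidden feature matrices for both node types at one layer."""

    H_drug: Tensor
    H_prot: Tensor
    layer: int = 0

    def validate(self) -> None:
        if self.H_drug.shape[1] != self.H_prot.shape[1]:
            raise ValueError("drug and protein states must share hidden dim")
        for H in (self.H_drug, self.H_prot):
            if not np.isfinite(H.data).all():
                raise FloatingPointError("non-finite node state")


@dataclass
class MsgParams:
    """Learned maps of one message-passing layer.

    f_dp transforms protein states flowing to drugs, f_pd drug states
    flowing to proteins, f_pp protein states flowing to proteins; eps_d /
    eps_p are the per-type self-loop maps. e_dti / e_ppi are the shared
    edge-type gate vectors (taken from the graph at init, then trained).
    """

    f_dp: Linear
    f_pd: Linear
    f_pp: Linear
    eps_d: Linear
    eps_p: Linear
    e_dti: Tensor
    e_ppi: Tensor

    def tensors(self, prefix: str) -> dict:
        out = {}
        for name in ("f_dp", "f_pd", "f_pp", "eps_d", "eps_p"):
            out.update(getattr(self, name).tensors(f"{prefix}.{name}"))
        out[f"{prefix}.e_dti"] = self.e_dti
        out[f"{prefix}.e_ppi"] = self.e_ppi
        return out


def init_msg_params(d: int, graph: HeteroGraph, rng: np.random.Generator) -> MsgParams:
    return MsgParams(
        f_dp=Linear(d, d, rng),
        f_pd=Linear(d, d, rng),
        f_pp=Linear(d, d, rng),
        eps_d=Linear(d, d, init="identity"),
        eps_p=Linear(d, d, init="identity"),
        e_dti=Tensor(np.asarray(graph.edge_feat["dti"], dtype=float).copy(), requires_grad=True),
        e_ppi=Tensor(np.asarray(graph.edge_feat["ppi"], dtype=float).copy(), requires_grad=True),
    )


# ---------------------------------------------------------------------------
# Per-node reference operations (numpy in, numpy out)


def _apply(linmap: Linear, h: np.ndarray) -> np.ndarray:
    out = h @ linmap.W.data
    if linmap.b is not None:
        out = out + linmap.b.data
    return out


def aggregate_drug(neighbor_prot_states, edge_feat, f_dp: Linear) -> np.ndarray:
    """Message to one drug: sum over protein neighbours of e * f_dp(h_j)."""
    e = np.asarray(edge_feat, dtype=float)
    msg = np.zeros_like(e)
    for h_j in neighbor_prot_states:
        msg = msg + e * _apply(f_dp, np.asarray(h_j, dtype=float))
    return msg


def aggregate_protein(neighbor_drug_states, neighbor_prot_states,
                      e_dti, e_ppi, f_pd: Linear, f_pp: Linear) -> np.ndarray:
    """Message to one protein: drug-neighbour term plus protein-neighbour term."""
    e_dti = np.asarray(e_dti, dtype=float)
    msg = np.zeros_like(e_dti)
    for h_i in neighbor_drug_states:
        msg = msg + e_dti * _apply(f_pd, np.asarray(h_i, dtype=float))
    e_ppi = np.asarray(e_ppi, dtype=float)
    for h_k in neighbor_prot_states:
        msg = msg + e_ppi * _apply(f_pp, np.asarray(h_k, dtype=float))
    return msg


def update_node(h_prev, message, eps_map: Linear) -> np.ndarray:
    """h_new = message + eps(h_prev)."""
    return np.asarray(message, dtype=float) + _apply(eps_map, np.asarray(h_prev, dtype=float))


def mp_layer_reference(graph: HeteroGraph, H_drug: np.ndarray, H_prot: np.ndarray,
                       params: MsgParams) -> tuple[np.ndarray, np.ndarray]:
    """Naive per-node double loop over the whole graph (test oracle)."""
    drug_nb = {i: [] for i in range(graph.n_drugs)}
    prot_nb_d = {j: [] for j in range(graph.n_proteins)}
    prot_nb_p = {j: [] for j in range(graph.n_proteins)}
    for d, p in graph.dti_edges:
        drug_nb[d].append(H_prot[p])
        prot_nb_d[p].append(H_drug[d])
    for i, j in graph.ppi_edges:
        prot_nb_p[i].append(H_prot[j])
        prot_nb_p[j].append(H_prot[i])

    e_dti, e_ppi = params.e_dti.data, params.e_ppi.data
    new_d = np.stack([
        update_node(H_drug[i], aggregate_drug(drug_nb[i], e_dti, params.f_dp), params.eps_d)
        for i in range(graph.n_drugs)
    ]) if graph.n_drugs else np.zeros_like(H_drug)
    new_p = np.stack([
        update_node(
            H_prot[j],
            aggregate_protein(prot_nb_d[j], prot_nb_p[j], e_dti, e_ppi, params.f_pd, params.f_pp),
            params.eps_p,
        )
        for j in range(graph.n_proteins)
    ]) if graph.n_proteins else np.zeros_like(H_prot)
    return new_d, new_p


# ---------------------------------------------------------------------------
# Vectorized layer (autodiff)


def mp_layer(graph: HeteroGraph, states: NodeStates, params: MsgParams) -> NodeStates:
    """One synchronous message-passing layer; cost linear in the edge count."""
    H_d, H_p = states.H_drug, states.H_prot
    n_d, n_p = graph.n_drugs, graph.n_proteins

    msg_d = Tensor(np.zeros(H_d.shape))
    msg_p = Tensor(np.zeros(H_p.shape))

    if graph.dti_edges:
        d_idx = np.array([e[0] for e in graph.dti_edges])
        p_idx = np.array([e[1] for e in graph.dti_edges])
        # protein -> drug
        proj = params.f_dp(H_p)
        msg_d = msg_d + ad.segment_sum(ad.gather_rows(proj, p_idx) * params.e_dti, d_idx, n_d)
        # drug -> protein
        proj = params.f_pd(H_d)
        msg_p = msg_p + ad.segment_sum(ad.gather_rows(proj, d_idx) * params.e_dti, p_idx, n_p)

    if graph.ppi_edges:
        i_idx = np.array([e[0] for e in graph.ppi_edges] + [e[1] for e in graph.ppi_edges])
        j_idx = np.array([e[1] for e in graph.ppi_edges] + [e[0] for e in graph.ppi_edges])
        proj = params.f_pp(H_p)
        msg_p = msg_p + ad.segment_sum(ad.gather_rows(proj, j_idx) * params.e_ppi, i_idx, n_p)

    out = NodeStates(
        H_drug=msg_d + params.eps_d(H_d),
        H_prot=msg_p + params.eps_p(H_p),
        layer=states.layer + 1,
    )
    out.validate()
    return out
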