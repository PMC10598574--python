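"""Low-rank global attention (LRGA).

Every node attends to every other node at cost linear in the node count:
with four width-k projections of the node features — M1 (query), M2 (key,
called the bond matrix here), M3 (value) and M4 (update) — the layer
computes

    LRGA(H) = [ (1/eta) * M1 (M2^T M3)  ||  M4 ],
    eta     = (1/n) (1^T M1)(M2^T 1) + eps_num,

associating the product as M1 @ (M2^T M3) so the only intermediates are
n x k and k x k; the n x n attention matrix of a standard transformer is
never materialized. M1 and M2 pass through a softplus so eta is a valid
(strictly positive) normalizer. A full layer concatenates the input
features, the LRGA output and the message-passing (GNN) output along the
feature axis and re-projects to the hidden width so layers can stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Tensor, as_tensor

__all__ = [
    "LRGAParams",
    "init_lrga_params",
    "project_heads",
    "eta",
    "lrga_attention",
    "lrga_layer",
]


@dataclass
class LRGAParams:
    """Four head projections R^d -> R^k (query, bond/key, value, update)."""

    m1: Linear
    m2: Linear
    m3: Linear
    m4: Linear
    eps_num: float = 1e-6
    split_mode: str = "project"  # "project" (learned) or "slice" (contiguous columns)

    def tensors(self, prefix: str) -> dict:
        out = {}
        if self.split_mode == "project":
            for name in ("m1", "m2", "m3", "m4"):
                out.update(getattr(self, name).tensors(f"{prefix}.{name}"))
        return out

    @property
    def k(self) -> int:
        return self.m1.W.shape[1]


def init_lrga_params(d: int, k: int, rng: np.random.Generator,
                     eps_num: float = 1e-6, split_mode: str = "project") -> LRGAParams:
    if split_mode == "slice" and d % 4 != 0:
        raise ValueError("slice mode requires hidden dim divisible by 4")
    return LRGAParams(
        m1=Linear(d, k, rng), m2=Linear(d, k, rng),
        m3=Linear(d, k, rng), m4=Linear(d, k, rng),
        eps_num=eps_num, split_mode=split_mode,
    )


def project_heads(H, params: LRGAParams):
    """Compute (M1, M2, M3, M4); M1 and M2 are softplus-activated (nonnegative)."""
    H = as_tensor(H)
    if params.split_mode == "slice":
        k = H.shape[1] // 4
        cols = [np.arange(i * k, (i + 1) * k) for i in range(4)]
        m1, m2, m3, m4 = (_slice_cols(H, c) for c in cols)
    else:
        m1, m2, m3, m4 = params.m1(H), params.m2(H), params.m3(H), params.m4(H)
    return ad.softplus(m1), ad.softplus(m2), m3, m4


def _slice_cols(H: Tensor, cols: np.ndarray) -> Tensor:
    return ad.gather_rows(H.T, cols).T


def eta(M1, M2, eps_num: float = 1e-6) -> Tensor:
    """Normalizer (1/n)(1^T M1)(M2^T 1) + eps_num, strictly positive for
    nonnegative M1, M2."""
    M1, M2 = as_tensor(M1), as_tensor(M2)
    n = M1.shape[0]
    s1 = M1.sum(axis=0)  # 1^T M1, shape (k,)
    s2 = M2.sum(axis=0)  # M2^T 1, shape (k,)
    return (s1 * s2).sum() / float(n) + Tensor(eps_num)


def lrga_attention(M1, M2, M3, M4, eta_val, probe: dict | None = None) -> Tensor:
    """[ (1/eta) M1 (M2^T M3) || M4 ]  (M4 may be None for the m4-free variant).

    The product is evaluated as M1 @ (M2^T @ M3): the k x k intermediate is
    formed first and no n x n matrix ever exists. With `probe` supplied,
    the largest intermediate's element count is recorded for cost audits.
    """
    M1, M2, M3 = as_tensor(M1), as_tensor(M2), as_tensor(M3)
    eta_val = as_tensor(eta_val)
    KV = M2.T @ M3                      # k x k
    left = (M1 @ KV) / eta_val          # n x k
    if probe is not None:
        n, k = M1.shape
        probe["intermediates"] = [KV.shape, left.shape]
        probe["max_intermediate"] = max(KV.data.size, left.data.size)
    if M4 is None:
        return left
    return ad.concat([left, as_tensor(M4)], axis=1)


def lrga_layer(H_l, gnn_out, params: LRGAParams, proj: Linear,
               use_m4: bool = True, probe: dict | None = None) -> Tensor:
    """Concatenate [H || LRGA(H) || GNN(H)] and re-project to the hidden width."""
    H_l, gnn_out = as_tensor(H_l), as_tensor(gnn_out)
    if H_l.shape[0] != gnn_out.shape[0]:
        raise ValueError("row-count mismatch between node features and GNN output")
    M1, M2, M3, M4 = project_heads(H_l, params)
    att = lrga_attention(M1, M2, M3, M4 if use_m4 else None,
                         eta(M1, M2, params.eps_num), probe=probe)
    return ad.relu(proj(ad.concat([H_l, att, gnn_out], axis=1)))
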