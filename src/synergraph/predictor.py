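"""Two-stage bilinear synergy predictor.

Stage 1 maps each drug of a pair, conditioned on the cell line, through a
shared MLP: X'_d = MLP([X_d || X_c]). The two stage-1 outputs are fused by
a low-rank bilinear operation — a shared linear projection of each branch,
an elementwise product and a bias — and stage 2 maps the fused vector,
again concatenated with the cell-line features, to the scalar synergy
score. With shared branch weights and Hadamard fusion the prediction is
exactly symmetric in the drug pair.

The first linear layer of each MLP is stored split by input part
(drug-derived block, cell block), which is algebraically identical to a
single matrix on the concatenation (W [x||c] = W_x x + W_c c) but lets the
training loop evaluate the cell part once per cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Tensor, as_tensor

__all__ = ["MLP", "PredictorParams", "init_predictor_params",
           "stage1", "bilinear_fuse", "predict_score"]


@dataclass
class MLP:
    """ReLU MLP whose first layer accepts pre-split input parts."""

    first: list          # one Linear per input part; only the first carries a bias
    hidden: list         # subsequent Linear layers (ReLU + dropout between)
    out: Linear
    dropout: float = 0.0

    def tensors(self, prefix: str) -> dict:
        d = {}
        for i, lin in enumerate(self.first):
            d.update(lin.tensors(f"{prefix}.first{i}"))
        for i, lin in enumerate(self.hidden):
            d.update(lin.tensors(f"{prefix}.hidden{i}"))
        d.update(self.out.tensors(f"{prefix}.out"))
        return d

    def forward_parts(self, parts, train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        if len(parts) != len(self.first):
            raise ValueError(f"expected {len(self.first)} input parts, got {len(parts)}")
        h = self.first[0](as_tensor(parts[0]))
        for lin, part in zip(self.first[1:], parts[1:]):
            h = h + lin(as_tensor(part))
        h = ad.relu(h)
        if train and self.dropout > 0:
            h = ad.dropout(h, self.dropout, rng)
        for lin in self.hidden:
            h = ad.relu(lin(h))
            if train and self.dropout > 0:
                h = ad.dropout(h, self.dropout, rng)
        return self.out(h)

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        """Apply to a single concatenated input (splits it by first-layer widths)."""
        x = as_tensor(x)
        widths = [lin.W.shape[0] for lin in self.first]
        parts, pos = [], 0
        for w in widths:
            parts.append(_cols(x, pos, pos + w))
            pos += w
        if pos != x.shape[-1]:
            raise ValueError(f"input width {x.shape[-1]} != expected {pos}")
        return self.forward_parts(parts, train=train, rng=rng)


def _cols(x: Tensor, start: int, stop: int) -> Tensor:
    return ad.gather_rows(x.T, np.arange(start, stop)).T


@dataclass
class PredictorParams:
    """Parameters of the two-stage predictor.

    The same `stage1` MLP serves both drug branches (weight sharing); `w`
    is the shared bilinear projection and `b` the bilinear bias. `fusion`
    selects Hadamard (default, symmetric), full outer-product bilinear, or
    plain concatenation (the MLP-only ablation).
    """

    stage1: MLP
    w: Linear
    b: Tensor
    stage2: MLP
    fusion: str = "hadamard"
    W_outer: Tensor | None = field(default=None)

    def tensors(self, prefix: str = "pred") -> dict:
        d = self.stage1.tensors(f"{prefix}.stage1")
        d.update(self.stage2.tensors(f"{prefix}.stage2"))
        if self.fusion == "hadamard":
            d.update(self.w.tensors(f"{prefix}.w"))
            d[f"{prefix}.b"] = self.b
        elif self.fusion == "outer":
            d[f"{prefix}.W_outer"] = self.W_outer
            d[f"{prefix}.b"] = self.b
        return d


def _build_mlp(part_dims, hidden_dims, n_out, dropout, rng) -> MLP:
    first = [Linear(part_dims[0], hidden_dims[0], rng)]
    first += [Linear(w, hidden_dims[0], rng, bias=False) for w in part_dims[1:]]
    hidden = [Linear(a, b, rng) for a, b in zip(hidden_dims, hidden_dims[1:])]
    return MLP(first=first, hidden=hidden, out=Linear(hidden_dims[-1], n_out, rng),
               dropout=dropout)


def init_predictor_params(f_drug: int, f_cell: int, config, rng: np.random.Generator
                          ) -> PredictorParams:
    """Build predictor parameters from a RunConfig's `predictor` section."""
    pc = getattr(config, "predictor", config)
    fusion = "concat" if getattr(getattr(config, "variant", None), "mlp_only", False) \
        else pc.fusion
    f1 = pc.stage1_out
    fb = pc.bilinear_dim if fusion != "concat" else 2 * f1
    params = PredictorParams(
        stage1=_build_mlp([f_drug, f_cell], list(pc.hidden_dims), f1, pc.dropout, rng),
        w=Linear(f1, pc.bilinear_dim, rng, bias=False),
        b=Tensor(np.zeros(pc.bilinear_dim), requires_grad=True),
        stage2=_build_mlp([fb, f_cell], list(pc.hidden_dims), 1, pc.dropout, rng),
        fusion=fusion,
    )
    if fusion == "outer":
        lim = np.sqrt(6.0 / (2 * f1))
        params.W_outer = Tensor(
            rng.uniform(-lim, lim, size=(f1, pc.bilinear_dim * f1)), requires_grad=True
        )
    return params


# ---------------------------------------------------------------------------


def stage1(X_d, X_c, params: PredictorParams, train: bool = False, rng=None) -> Tensor:
    """X'_d = MLP([X_d || X_c]), shared across the two drug branches."""
    return params.stage1.forward_parts([as_tensor(X_d), as_tensor(X_c)],
                                       train=train, rng=rng)


def bilinear_fuse(Xa, Xb, params: PredictorParams) -> Tensor:
    """Fuse the two stage-1 drug representations.

    hadamard: (w Xa) * (w Xb) + b          (symmetric)
    outer:    full bilinear Xa^T W_m Xb + b_m per output m (not symmetric
              unless each W_m is)
    concat:   [Xa || Xb]                   (MLP-only ablation)
    """
    Xa, Xb = as_tensor(Xa), as_tensor(Xb)
    if params.fusion == "hadamard":
        return params.w(Xa) * params.w(Xb) + params.b
    if params.fusion == "outer":
        f1 = Xa.shape[-1]
        fb = params.b.shape[0]
        # (n, f1) @ (f1, fb*f1) -> (n, fb, f1); contract with Xb
        P = (Xa @ params.W_outer).reshape(-1, fb, f1)
        return (P * Xb.reshape(-1, 1, f1)).sum(axis=2) + params.b
    if params.fusion == "concat":
        return ad.concat([Xa, Xb], axis=-1)
    raise ValueError(f"unknown fusion {params.fusion!r}")


def predict_score(X_ab, X_c, params: PredictorParams, train: bool = False, rng=None) -> Tensor:
    """Scalar synergy score for the fused pair on cell line c."""
    out = params.stage2.forward_parts([as_tensor(X_ab), as_tensor(X_c)],
                                      train=train, rng=rng)
    return out.reshape(-1) if out.ndim > 1 else out
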