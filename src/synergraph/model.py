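"""End-to-end synergy regression model.

`SynergyModel` bundles the heterogeneous graph, the raw feature matrices
and the synergy records; `fit()` trains the full pipeline — typed message
passing interleaved with low-rank global attention, then the two-stage
bilinear predictor — under Smooth L1 (or MSE) loss with Adam, early
stopping on validation MSE, and returns a `SynergyResults` carrying the
trained parameters, per-split metrics, training history and prediction /
plotting helpers. `ablate` reruns the model and its seven architecture /
loss variants under one shared seed and split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Linear, Tensor, clip_global_norm
from .config import RunConfig, subseed, substream
from .evaluation import EvalReport, grouped_eval, metrics, split_622
from .exceptions import ConfigError, SynergraphError, ValidationError
from .featurize import FeatureBundle, assemble_bundle
from .io import (HeteroGraph, build_heterograph, read_drug_table, read_edge_list,
                 read_expression, read_fasta, read_synergy_table)
from .lrga import LRGAParams, eta, init_lrga_params, lrga_attention, project_heads
from .msgpass import MsgParams, NodeStates, init_msg_params, mp_layer
from .predictor import PredictorParams, init_predictor_params

logger = logging.getLogger(__name__)

__all__ = ["SynergyModel", "SynergyResults", "ablate", "VARIANTS"]

#: the seven ablation variants, in report order after the default
VARIANTS = {
    "mse_loss": {"mse_loss": True},
    "fps_only": {"fps_only": True},
    "no_ppi": {"no_ppi": True},
    "gnn_only": {"gnn_only": True},
    "gat": {"gat": True},
    "no_m4": {"no_m4": True},
    "mlp_only": {"mlp_only": True},
}


@dataclass
class GATParams:
    """Single-head graph attention used by the GAT ablation variant."""

    W: Linear
    a_src: Tensor
    a_dst: Tensor

    def tensors(self, prefix: str) -> dict:
        out = self.W.tensors(f"{prefix}.W")
        out[f"{prefix}.a_src"] = self.a_src
        out[f"{prefix}.a_dst"] = self.a_dst
        return out


@dataclass
class LayerParams:
    msg: MsgParams
    lrga: LRGAParams | None
    gat: GATParams | None
    proj_d: Linear
    proj_p: Linear

    def tensors(self, prefix: str) -> dict:
        out = self.msg.tensors(f"{prefix}.msg")
        if self.lrga is not None:
            out.update(self.lrga.tensors(f"{prefix}.lrga"))
        if self.gat is not None:
            out.update(self.gat.tensors(f"{prefix}.gat"))
        out.update(self.proj_d.tensors(f"{prefix}.proj_d"))
        out.update(self.proj_p.tensors(f"{prefix}.proj_p"))
        return out


@dataclass
class ModelParams:
    in_d: Linear
    in_p: Linear
    prot_embed: Tensor
    layers: list
    pred: PredictorParams

    def flat(self) -> dict:
        out = self.in_d.tensors("in_d")
        out.update(self.in_p.tensors("in_p"))
        out["prot_embed"] = self.prot_embed
        for i, lp in enumerate(self.layers):
            out.update(lp.tensors(f"layer{i}"))
        out.update(self.pred.tensors("pred"))
        return out


def _gat_layer(H_all: Tensor, mask: np.ndarray, params: GATParams) -> Tensor:
    """Dense masked single-head attention (adequate at the graph sizes the
    variant is run on; the low-rank layer is the linear-cost path)."""
    Hw = params.W(H_all)                                   # n x kg
    n = Hw.shape[0]
    s_src = (Hw * params.a_src).sum(axis=1).reshape(n, 1)
    s_dst = (Hw * params.a_dst).sum(axis=1).reshape(1, n)
    scores = ad.leaky_relu(s_src + s_dst)
    neg = np.where(mask, 0.0, -1e30)
    scores = scores * Tensor(mask.astype(float)) + Tensor(neg)
    shift = scores.data.max(axis=1, keepdims=True)         # detached; softmax shift-invariant
    e = ad.exp(scores - Tensor(shift))
    alpha = e / e.sum(axis=1, keepdims=True)
    return alpha @ Hw


class SynergyModel:
    """Synergy regression on a heterogeneous drug-protein graph.

    Parameters
    ----------
    graph : HeteroGraph
    bundle : FeatureBundle
        Row-aligned raw features for drugs, proteins and cell lines.
    records : list of SynergyRecord
    config : RunConfig, optional
    tissue_map : dict, optional
        cell line id -> tissue, for grouped evaluation.
    """

    def __init__(self, graph: HeteroGraph, bundle: FeatureBundle, records,
                 config: RunConfig | None = None, tissue_map: dict | None = None):
        self.config = config or RunConfig()
        self.graph = graph
        self.bundle = bundle
        self.records = list(records)
        self.tissue_map = tissue_map
        if not self.records:
            raise ValidationError("no synergy records")
        v = self.config.variant
        if v.gnn_only and v.gat:
            raise ConfigError("gnn_only and gat variants are mutually exclusive")

        drug_index = {d: i for i, d in enumerate(graph.drug_ids)}
        cell_index = {c: i for i, c in enumerate(bundle.cell_ids)}
        try:
            self._ai = np.array([drug_index[r.drug_a] for r in self.records])
            self._bi = np.array([drug_index[r.drug_b] for r in self.records])
            self._ci = np.array([cell_index[r.cell_line] for r in self.records])
        except KeyError as exc:
            raise ValidationError(f"record references unknown id {exc.args[0]!r}") from None
        tgt = self.config.train.target_score
        self._y = np.array([r.scores[tgt] for r in self.records])

        # effective graph under the PPI ablation
        self._graph_eff = graph
        if v.no_ppi:
            self._graph_eff = HeteroGraph(
                drug_ids=graph.drug_ids, protein_ids=graph.protein_ids,
                dti_edges=[] if v.no_ppi_drops_dti else list(graph.dti_edges),
                ppi_edges=[], edge_feat=graph.edge_feat,
            )

        # constant feature tensors; the protein embedding block is trainable
        emb = bundle.prot_blocks["embedding"]
        self._Xd = Tensor(bundle.X_drug)
        self._Xp_seq = Tensor(bundle.X_prot[:, : emb.start])
        self._prot_embed_init = bundle.X_prot[:, emb]
        self._Xc = Tensor(bundle.X_cell)

        if v.gat:
            nd, npr = graph.n_drugs, graph.n_proteins
            n = nd + npr
            mask = np.eye(n, dtype=bool)
            for d, p in self._graph_eff.dti_edges:
                mask[d, nd + p] = mask[nd + p, d] = True
            for i, j in self._graph_eff.ppi_edges:
                mask[nd + i, nd + j] = mask[nd + j, nd + i] = True
            self._gat_mask = mask

    # ------------------------------------------------------------------
    @classmethod
    def from_directory(cls, path, config: RunConfig | None = None,
                       tissue_map: dict | None = None) -> "SynergyModel":
        """Build from a directory holding drugs.csv, proteins.fasta, dti.tsv,
        ppi.tsv, expression.csv and synergy.csv."""
        from pathlib import Path

        path = Path(path)
        config = config or RunConfig()
        drugs = read_drug_table(path / "drugs.csv")
        proteins = read_fasta(path / "proteins.fasta")
        dti = read_edge_list(path / "dti.tsv", drugs["id"], proteins["id"])
        ppi = read_edge_list(path / "ppi.tsv", proteins["id"], proteins["id"],
                             undirected=True)
        expression = read_expression(path / "expression.csv")
        config.featurize.cell_n_genes = expression.shape[1]
        records = read_synergy_table(path / "synergy.csv", drugs["id"],
                                     expression.index)
        graph = build_heterograph(drugs, proteins, dti, ppi,
                                  edge_dim=config.edge_dim or config.lrga.hidden_dim,
                                  seed=subseed(config.seed, "init"))
        bundle = assemble_bundle(drugs, proteins, expression, config)
        return cls(graph, bundle, records, config, tissue_map)

    # ------------------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> ModelParams:
        cfg, v = self.config, self.config.variant
        d, k = cfg.lrga.hidden_dim, cfg.lrga.head_dim_k
        k_gat = 2 * k
        if v.gnn_only:
            width = 2 * d
        elif v.gat:
            width = 2 * d + k_gat
        elif v.no_m4:
            width = 2 * d + k
        else:
            width = 2 * d + 2 * k

        layers = []
        for _ in range(cfg.lrga.n_layers):
            lrga_p = gat_p = None
            if v.gat:
                gat_p = GATParams(W=Linear(d, k_gat, rng, bias=False),
                                  a_src=Tensor(rng.normal(0, 0.1, k_gat), requires_grad=True),
                                  a_dst=Tensor(rng.normal(0, 0.1, k_gat), requires_grad=True))
            elif not v.gnn_only:
                lrga_p = init_lrga_params(d, k, rng, cfg.lrga.eps_num, cfg.lrga.split_mode)
            layers.append(LayerParams(
                msg=init_msg_params(d, self._graph_eff, rng),
                lrga=lrga_p, gat=gat_p,
                proj_d=Linear(width, d, rng), proj_p=Linear(width, d, rng),
            ))
        return ModelParams(
            in_d=Linear(self.bundle.X_drug.shape[1], d, rng),
            in_p=Linear(self._Xp_seq.shape[1] + self._prot_embed_init.shape[1], d, rng),
            prot_embed=Tensor(self._prot_embed_init.copy(), requires_grad=True),
            layers=layers,
            pred=init_predictor_params(d, self.bundle.X_cell.shape[1], cfg, rng),
        )

    def _encode(self, params: ModelParams) -> Tensor:
        """Drug embeddings from the graph encoder (N_d x d)."""
        v = self.config.variant
        Xp = ad.concat([self._Xp_seq, params.prot_embed], axis=1)
        H_d = ad.relu(params.in_d(self._Xd))
        H_p = ad.relu(params.in_p(Xp))
        nd = self.graph.n_drugs
        for lp in params.layers:
            states = mp_layer(self._graph_eff, NodeStates(H_d, H_p), lp.msg)
            gnn_d, gnn_p = states.H_drug, states.H_prot
            if v.gnn_only:
                blocks_d, blocks_p = [H_d, gnn_d], [H_p, gnn_p]
            else:
                H_all = ad.concat([H_d, H_p], axis=0)
                if v.gat:
                    att = _gat_layer(H_all, self._gat_mask, lp.gat)
                else:
                    M1, M2, M3, M4 = project_heads(H_all, lp.lrga)
                    att = lrga_attention(M1, M2, M3,
                                         None if v.no_m4 else M4,
                                         eta(M1, M2, lp.lrga.eps_num))
                att_d = ad.gather_rows(att, np.arange(nd))
                att_p = ad.gather_rows(att, nd + np.arange(self.graph.n_proteins))
                blocks_d, blocks_p = [H_d, att_d, gnn_d], [H_p, att_p, gnn_p]
            H_d = ad.relu(lp.proj_d(ad.concat(blocks_d, axis=1)))
            H_p = ad.relu(lp.proj_p(ad.concat(blocks_p, axis=1)))
        return H_d

    def _scores(self, params: ModelParams, idx: np.ndarray, E: Tensor | None = None,
                train: bool = False, rng=None) -> Tensor:
        """Predicted synergy for the records at `idx`."""
        from .predictor import bilinear_fuse

        if E is None:
            E = self._encode(params)
        pred = params.pred
        ai, bi, ci = self._ai[idx], self._bi[idx], self._ci[idx]

        p_in = self.config.predictor.input_dropout

        def _stage(mlp, drug_part, cell_idx):
            # first layer split by input part: cell contribution computed once
            # over all cell lines, then gathered per record
            cell_src = self._Xc
            if train and p_in > 0:
                drug_part = ad.dropout(drug_part, p_in, rng)
                cell_src = ad.dropout(cell_src, p_in, rng)
            cell_all = mlp.first[1](cell_src)
            h = ad.relu(mlp.first[0](drug_part) + ad.gather_rows(cell_all, cell_idx))
            if train and mlp.dropout > 0:
                h = ad.dropout(h, mlp.dropout, rng)
            for lin in mlp.hidden:
                h = ad.relu(lin(h))
                if train and mlp.dropout > 0:
                    h = ad.dropout(h, mlp.dropout, rng)
            return mlp.out(h)

        Xa = _stage(pred.stage1, ad.gather_rows(E, ai), ci)
        Xb = _stage(pred.stage1, ad.gather_rows(E, bi), ci)
        fused = bilinear_fuse(Xa, Xb, pred)
        return _stage(pred.stage2, fused, ci).reshape(-1)

    # ------------------------------------------------------------------
    def fit(self, verbose: bool = False) -> "SynergyResults":
        cfg = self.config
        tr = cfg.train
        idx_train, idx_val, idx_test = split_622(
            list(range(len(self.records))), tr.split_ratios, subseed(cfg.seed, "split")
        )
        idx_train, idx_val, idx_test = map(np.asarray, (idx_train, idx_val, idx_test))

        params = self._init_params(substream(cfg.seed, "init"))
        flat = params.flat()
        opt = Adam(flat, lr=tr.learning_rate, weight_decay=tr.weight_decay)
        rng_batch = substream(cfg.seed, "batching")
        rng_drop = substream(cfg.seed, "dropout")
        y = self._y

        def eval_mse(idx):
            pred = self._scores(params, idx).data
            return float(np.mean((pred - y[idx]) ** 2))

        best_val, best_state, best_epoch = np.inf, None, -1
        last_decay = -1
        history = []
        for epoch in range(tr.epochs):
            order = rng_batch.permutation(len(idx_train))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), tr.batch_size):
                batch = idx_train[order[start : start + tr.batch_size]]
                opt.zero_grad()
                pred = self._scores(params, batch, train=True, rng=rng_drop)
                resid = pred - Tensor(y[batch])
                if tr.loss == "mse":
                    loss = (resid * resid).mean()
                else:
                    loss = ad.smooth_l1(pred, Tensor(y[batch])).mean()
                if not np.isfinite(loss.data):
                    raise SynergraphError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                loss.backward()
                clip_global_norm(flat, tr.clip_norm)
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            val_mse = eval_mse(idx_val)
            history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                            "val_mse": val_mse})
            if verbose:
                logger.info("epoch %d: train loss %.4f, val MSE %.4f",
                            epoch, epoch_loss / n_batches, val_mse)
            if val_mse < best_val - 1e-12:
                best_val, best_epoch = val_mse, epoch
                best_state = {k: t.data.copy() for k, t in flat.items()}
            elif epoch - best_epoch >= tr.patience:
                break
            if (tr.lr_decay < 1.0
                    and epoch - max(best_epoch, last_decay) >= tr.lr_patience
                    and opt.lr > tr.min_lr):
                opt.lr = max(tr.min_lr, opt.lr * tr.lr_decay)
                last_decay = epoch
        if best_state is not None:
            for k, t in flat.items():
                t.data = best_state[k]

        report = EvalReport(history=history)
        E = self._encode(params)
        preds = {}
        for name, idx in (("train", idx_train), ("val", idx_val), ("test", idx_test)):
            preds[name] = self._scores(params, idx, E=E).data
            report.splits[name] = metrics(preds[name], y[idx])
        return SynergyResults(self, params, report, preds,
                              {"train": idx_train, "val": idx_val, "test": idx_test})


class SynergyResults:
    """Fitted model: trained parameters, metrics, history, predictions."""

    def __init__(self, model: SynergyModel, params: ModelParams,
                 report: EvalReport, preds: dict, split_idx: dict):
        self.model = model
        self.params = params
        self.report = report
        self.preds = preds
        self.split_idx = split_idx
        self.config = model.config

    # -- accessors ------------------------------------------------------
    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.report.history)

    def predict(self, triples) -> np.ndarray:
        """Predict synergy for (drug_a, drug_b, cell_line) triples.

        `triples` is a DataFrame with those columns or an iterable of
        3-tuples of ids known to the model.
        """
        if isinstance(triples, pd.DataFrame):
            triples = triples[["drug_a", "drug_b", "cell_line"]].itertuples(index=False)
        triples = list(triples)
        m = self.model
        drug_index = {d: i for i, d in enumerate(m.graph.drug_ids)}
        cell_index = {c: i for i, c in enumerate(m.bundle.cell_ids)}
        try:
            ai = np.array([drug_index[a] for a, _, _ in triples])
            bi = np.array([drug_index[b] for _, b, _ in triples])
            ci = np.array([cell_index[c] for _, _, c in triples])
        except KeyError as exc:
            raise ValidationError(f"unknown id {exc.args[0]!r}") from None
        # reuse the batched scorer through temporary index arrays
        saved = (m._ai, m._bi, m._ci)
        try:
            m._ai, m._bi, m._ci = ai, bi, ci
            out = m._scores(self.params, np.arange(len(triples))).data
        finally:
            m._ai, m._bi, m._ci = saved
        return out

    def grouped(self, group_by: str = "cell_line",
                tissue_map: dict | None = None, split: str = "test") -> pd.DataFrame:
        idx = self.split_idx[split]
        recs = [self.model.records[i] for i in idx]
        table = grouped_eval(self.preds[split], recs, group_by,
                             tissue_map or self.model.tissue_map,
                             target=self.config.train.target_score)
        self.report.groups[group_by] = table
        return table

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Synergy regression results",
            "==========================",
            f"drugs: {self.model.graph.n_drugs}   proteins: {self.model.graph.n_proteins}"
            f"   cell lines: {len(self.model.bundle.cell_ids)}"
            f"   records: {len(self.model.records)}",
            f"target score: {cfg.train.target_score}   loss: {cfg.train.loss}"
            f"   seed: {cfg.seed}",
            f"hidden dim: {cfg.lrga.hidden_dim}   head dim k: {cfg.lrga.head_dim_k}"
            f"   layers: {cfg.lrga.n_layers}   fusion: {self.params.pred.fusion}",
            f"epochs run: {len(self.report.history)}",
            "",
            self.report.to_frame().round(4).to_string(),
        ]
        flags = [k for k, on in self.config.variant.model_dump().items() if on]
        if flags:
            lines.insert(2, f"variant flags: {', '.join(flags)}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def save(self, outdir) -> None:
        from pathlib import Path
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "params.npz",
                 **{k: t.data for k, t in self.params.flat().items()})
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.model_dump(), fh)
        self.report.to_json(outdir / "report.json")

    @classmethod
    def load(cls, model: SynergyModel, outdir) -> "SynergyResults":
        from pathlib import Path

        params = model._init_params(substream(model.config.seed, "init"))
        flat = params.flat()
        with np.load(Path(outdir) / "params.npz") as data:
            for k, t in flat.items():
                if k not in data or data[k].shape != t.data.shape:
                    raise ValidationError(f"saved parameter {k!r} missing or mis-shaped")
                t.data = data[k].copy()
        return cls(model, params, EvalReport(), {}, {})

    # -- plotting -------------------------------------------------------
    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["epoch"], h["train_loss"], label="train loss")
        ax.plot(h["epoch"], h["val_mse"], label="val MSE")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def plot_pred_vs_true(self, split: str = "test", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = self.split_idx[split]
        ax.scatter(self.model._y[idx], self.preds[split], s=8, alpha=0.6)
        lims = [self.model._y[idx].min(), self.model._y[idx].max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("true synergy")
        ax.set_ylabel("predicted synergy")
        ax.set_title(split)
        return ax


# ---------------------------------------------------------------------------


def ablate(base_config: RunConfig, drugs: pd.DataFrame, proteins: pd.DataFrame,
           dti_edges, ppi_edges, expression: pd.DataFrame, records,
           verbose: bool = False) -> pd.DataFrame:
    """Run the default model plus its seven variants under one seed/split.

    Returns an 8-row table (default first) of test metrics. A variant
    that fails is recorded with NaN metrics and the error message; the
    remaining variants still run.
    """
    rows = {}
    for name, flags in [("default", {})] + list(VARIANTS.items()):
        cfg = base_config.with_variant(**flags)
        cfg.featurize.cell_n_genes = expression.shape[1]
        try:
            graph = build_heterograph(drugs, proteins, dti_edges, ppi_edges,
                                      edge_dim=cfg.edge_dim or cfg.lrga.hidden_dim,
                                      seed=subseed(cfg.seed, "init"))
            bundle = assemble_bundle(drugs, proteins, expression, cfg)
            res = SynergyModel(graph, bundle, records, cfg).fit(verbose=verbose)
            rows[name] = {**res.report.splits["test"], "error": ""}
        except Exception as exc:  # noqa: BLE001 - variant isolation is the contract
            logger.error("variant %r failed: %s", name, exc)
            rows[name] = {"MSE": np.nan, "RMSE": np.nan, "R2": np.nan,
                          "PCC": np.nan, "error": str(exc)}
    return pd.DataFrame(rows).T[["MSE", "RMSE", "R2", "PCC", "error"]]
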