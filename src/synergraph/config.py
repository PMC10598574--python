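"""Run configuration: every architecture/training choice as one validated object.

A `RunConfig` is a nested pydantic model; YAML files are loaded with
defaults filled, unknown keys rejected and cross-field invariants checked.
A single global seed fans out deterministically to per-stage substreams
(via `numpy.random.SeedSequence`), so toggling one stage never shifts
another stage's randomness.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .exceptions import ConfigError

__all__ = ["RunConfig", "GenConfig", "load_config", "substream", "subseed"]

_STREAMS = ("split", "init", "batching", "dropout", "generate", "eval")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FeaturizeConfig(_Section):
    fingerprint_nbits: int = 1024
    onehot_alphabet: Optional[list[str]] = None  # None -> built-in 64-char set + UNK
    onehot_max_len: int = 100
    descriptor_names: Optional[list[str]] = None  # None -> the 8 defaults
    protein_embed_dim: int = 32
    cell_n_genes: int = 1956


class LrgaConfig(_Section):
    hidden_dim: int = 64
    head_dim_k: int = 16
    n_layers: int = 2
    use_m4: bool = True
    eps_num: float = 1e-6
    split_mode: Literal["project", "slice"] = "project"


class PredictorConfig(_Section):
    hidden_dims: list[int] = Field(default_factory=lambda: [128, 64])
    stage1_out: int = 32
    bilinear_dim: int = 32
    fusion: Literal["hadamard", "outer", "concat"] = "hadamard"
    share_branches: bool = True
    dropout: float = 0.2
    input_dropout: float = 0.2


class TrainConfig(_Section):
    loss: Literal["smooth_l1", "mse"] = "smooth_l1"
    target_score: Literal["css", "s", "zip", "bliss", "loewe", "hsa"] = "loewe"
    split_ratios: list[float] = Field(default_factory=lambda: [0.6, 0.2, 0.2])
    optimizer: Literal["adam"] = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 600
    batch_size: int = 256
    patience: int = 100
    lr_decay: float = 1.0        # < 1 enables decay when validation stalls
    lr_patience: int = 50        # epochs without val improvement before decay
    min_lr: float = 1e-5
    clip_norm: float = 5.0


class VariantConfig(_Section):
    """Architecture/loss ablation switches (all off = the full model)."""

    fps_only: bool = False
    no_ppi: bool = False
    no_ppi_drops_dti: bool = False
    gnn_only: bool = False
    gat: bool = False
    no_m4: bool = False
    mlp_only: bool = False
    mse_loss: bool = False


class RunConfig(_Section):
    seed: int = 0
    edge_dim: Optional[int] = None  # None -> lrga.hidden_dim
    featurize: FeaturizeConfig = Field(default_factory=FeaturizeConfig)
    lrga: LrgaConfig = Field(default_factory=LrgaConfig)
    predictor: PredictorConfig = Field(default_factory=PredictorConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    variant: VariantConfig = Field(default_factory=VariantConfig)

    def model_post_init(self, _ctx) -> None:
        problems = []
        if self.lrga.head_dim_k > self.lrga.hidden_dim:
            problems.append("lrga.head_dim_k exceeds lrga.hidden_dim")
        if len(self.train.split_ratios) != 3 or any(r <= 0 for r in self.train.split_ratios):
            problems.append("train.split_ratios must be 3 positive numbers")
        if not 0 <= self.predictor.dropout < 1:
            problems.append("predictor.dropout must be in [0,1)")
        if problems:
            raise ConfigError("; ".join(problems))
        total = sum(self.train.split_ratios)
        self.train.split_ratios = [r / total for r in self.train.split_ratios]
        if self.variant.mse_loss:
            self.train.loss = "mse"

    def with_variant(self, **flags) -> "RunConfig":
        """Copy of this config with the given variant flags set."""
        cfg = self.model_dump()
        cfg["variant"] = {**cfg["variant"], **flags}
        return RunConfig(**cfg)


class GenConfig(_Section):
    """Synthetic dataset shape and planted-mechanism parameters."""

    n_drugs: int = 52
    n_proteins: int = 200
    n_cells: int = 60
    n_genes: int = 1956
    n_records: int = 2000
    latent_dim: int = 2
    dti_density: float = 0.05
    ppi_density: float = 0.04
    noise_sd: Optional[float] = None   # None -> 10% of the SD of noiseless scores
    alpha: float = 0.8                 # bilinear interaction strength
    beta: float = 1.2                  # additive drug-cell coupling strength
    expr_noise_sd: float = 0.5
    seed: int = 0

    def model_post_init(self, _ctx) -> None:
        problems = []
        for name in ("n_drugs", "n_proteins", "n_cells", "n_genes"):
            if getattr(self, name) < 2:
                problems.append(f"{name} must be >= 2")
        for name in ("dti_density", "ppi_density"):
            if not 0 < getattr(self, name) <= 1:
                problems.append(f"{name} must be in (0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))


def load_config(path=None, cls=RunConfig, **overrides):
    """Load a YAML config (empty/missing -> all defaults), rejecting unknown keys."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    data.update(overrides)
    try:
        return cls(**data)
    except PydanticValidationError as exc:
        msgs = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ConfigError("invalid config: " + "; ".join(msgs)) from None


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from the global seed."""
    if stage not in _STREAMS:
        raise ConfigError(f"unknown random stream {stage!r}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(stage),))
    )


def subseed(seed: int, stage: str) -> int:
    """A plain integer sub-seed (< 2^31) for APIs that take one."""
    return int(substream(seed, stage).integers(0, 2**31 - 1))
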