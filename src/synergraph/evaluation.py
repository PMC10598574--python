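"""Loss, data splitting, regression metrics and grouped evaluation."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_squared_error, r2_score

from .exceptions import ConfigError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["smooth_l1", "split_622", "metrics", "EvalReport", "grouped_eval"]


def smooth_l1(pred, true) -> float | np.ndarray:
    """Robust regression loss: 0.5 r^2 if |r| < 1 else |r| - 0.5, r = pred - true.

    Quadratic near zero, linear in the tails, continuous at |r| = 1 where
    both branches equal 0.5; its derivative is bounded by 1 in magnitude.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if not (np.isfinite(pred).all() and np.isfinite(true).all()):
        raise ValidationError("non-finite input to smooth_l1")
    r = pred - true
    out = np.where(np.abs(r) < 1.0, 0.5 * r * r, np.abs(r) - 0.5)
    return float(out) if out.ndim == 0 else out


def split_622(records: list, ratios=(0.6, 0.2, 0.2), seed: int = 0):
    """Seeded uniform shuffle into train/val/test of sizes
    floor(r1*n) / floor(r2*n) / remainder."""
    n = len(records)
    if n < 5:
        raise ValidationError(f"need at least 5 records to split, got {n}")
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ConfigError("split ratios must be positive")
    ratios = ratios / ratios.sum()
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    pick = lambda idx: [records[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


def metrics(pred, true) -> dict:
    """MSE, RMSE, R^2 and Pearson correlation of predictions vs truth."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValidationError("pred/true must be equal-length 1-D vectors")
    if len(pred) < 2:
        raise ValidationError("metrics need at least 2 points")
    mse = mean_squared_error(true, pred)
    out = {"MSE": float(mse), "RMSE": float(np.sqrt(mse))}
    if np.std(true) == 0:
        logger.warning("constant truth vector: R2/PCC undefined, reporting NaN")
        out["R2"] = float("nan")
        out["PCC"] = float("nan")
    else:
        out["R2"] = float(r2_score(true, pred))
        if np.std(pred) == 0:
            logger.warning("constant predictions: PCC undefined, reporting NaN")
            out["PCC"] = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out["PCC"] = float(stats.pearsonr(pred, true)[0])
    return out


@dataclass
class EvalReport:
    """Per-split metrics plus optional per-group breakdowns."""

    splits: dict = field(default_factory=dict)     # {"train"/"val"/"test": metric dict}
    groups: dict = field(default_factory=dict)     # {"cell_line"/"tissue": DataFrame}
    history: list = field(default_factory=list)    # per-epoch training log

    def to_json(self, path) -> None:
        payload = {
            "splits": self.splits,
            "groups": {k: v.to_dict(orient="index") for k, v in self.groups.items()},
            "history": self.history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.splits).T


def grouped_eval(pred, records: list, group_by: str = "cell_line",
                 tissue_map: dict | None = None, target: str = "loewe") -> pd.DataFrame:
    """Per-group metric table over cell lines or tissues.

    Groups with fewer than 2 records are skipped with a warning; cell
    lines absent from `tissue_map` fall into an "unknown" tissue group.
    """
    pred = np.asarray(pred, dtype=float)
    if group_by not in ("cell_line", "tissue"):
        raise ConfigError(f"unknown group key {group_by!r}")
    if group_by == "tissue" and tissue_map is None:
        raise ConfigError("tissue grouping requires a tissue_map")

    def key(rec):
        if group_by == "cell_line":
            return rec.cell_line
        if rec.cell_line not in tissue_map:
            logger.warning("cell line %r missing from tissue map; grouped as unknown",
                           rec.cell_line)
            return "unknown"
        return tissue_map[rec.cell_line]

    buckets: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        buckets.setdefault(key(rec), []).append(i)

    rows = {}
    for group, idx in sorted(buckets.items()):
        if len(idx) < 2:
            logger.warning("group %r has %d record(s); skipped", group, len(idx))
            continue
        idx = np.asarray(idx)
        true = np.array([records[i].scores[target] for i in idx])
        rows[group] = {"n": len(idx), **metrics(pred[idx], true)}
    return pd.DataFrame(rows).T
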