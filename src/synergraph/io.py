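"""Data model and file I/O for the heterogeneous drug-protein graph.

The tool consumes five plain-text inputs: a drug table (CSV ``id,smiles``),
protein sequences (FASTA), drug-target and protein-protein edge lists
(2-column TSV), a cell-line expression matrix (CSV, first column the
cell-line id), and a DrugComb-style synergy table (CSV with six score
columns). Node identifiers are opaque strings; indices are assigned by
file order and never serialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("css", "s", "zip", "bliss", "loewe", "hsa")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

__all__ = [
    "SCORE_COLUMNS",
    "HeteroGraph",
    "SynergyRecord",
    "read_drug_table",
    "write_drug_table",
    "read_fasta",
    "write_fasta",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "read_synergy_table",
    "write_synergy_table",
    "build_heterograph",
]


@dataclass(frozen=True)
class SynergyRecord:
    """One measured drug pair on a cell line with its six synergy scores.

    ``label`` marks the combination as synergistic when its Loewe score is
    strictly positive.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    scores: dict
    label: bool = field(default=False)

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValidationError(f"self-combination {self.drug_a!r} is not a drug pair")
        missing = [k for k in SCORE_COLUMNS if k not in self.scores]
        if missing:
            raise ValidationError(f"record {self.drug_a}/{self.drug_b}: missing scores {missing}")
        object.__setattr__(self, "label", float(self.scores["loewe"]) > 0.0)


@dataclass
class HeteroGraph:
    """Typed graph over drug and protein nodes.

    Drug-target (DTI) edges link a drug index to a protein index and are
    traversed in both directions during message passing. Protein-protein
    (PPI) edges are undirected and stored with the smaller index first.
    Self-loops are never stored: the update rule handles each node's own
    state through a separate self-loop map. ``edge_feat`` holds one
    feature vector per edge *type* (shared by every edge of that type).
    """

    drug_ids: list
    protein_ids: list
    dti_edges: list          # list[(drug_idx, protein_idx)]
    ppi_edges: list          # list[(protein_idx, protein_idx)], i < j
    edge_feat: dict          # {"dti": (d_e,), "ppi": (d_e,)}

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def validate(self) -> None:
        nd, np_ = self.n_drugs, self.n_proteins
        for d, p in self.dti_edges:
            if not (0 <= d < nd and 0 <= p < np_):
                raise ValidationError(f"DTI edge ({d},{p}) out of range")
        for i, j in self.ppi_edges:
            if i == j:
                raise ValidationError(f"PPI self-loop ({i},{i}) is not allowed")
            if not (0 <= i < np_ and 0 <= j < np_):
                raise ValidationError(f"PPI edge ({i},{j}) out of range")


# ---------------------------------------------------------------------------
# Readers / writers


def read_drug_table(path) -> pd.DataFrame:
    """Read a CSV with columns ``id,smiles``; row order is preserved."""
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty drug table")
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate drug ids {dupes}")
    if df["smiles"].isna().any() or (df["smiles"].str.len() == 0).any():
        raise ValidationError(f"{path}: empty SMILES entries")
    return df[["id", "smiles"]].reset_index(drop=True)


def write_drug_table(df: pd.DataFrame, path) -> None:
    df[["id", "smiles"]].to_csv(path, index=False)


def read_fasta(path) -> pd.DataFrame:
    """Read protein sequences; ids are the first token of each header."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) == 0:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValidationError(f"{path}: illegal residues {sorted(bad)} in {rec.id!r}")
        rows.append((rec.id, seq))
    if not rows:
        raise ValidationError(f"{path}: no FASTA records")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate protein ids")
    return pd.DataFrame(rows, columns=["id", "sequence"])


def write_fasta(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f">{row['id']}\n")
            seq = row["sequence"]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_edge_list(path, valid_src, valid_dst, undirected: bool = False) -> list:
    """Read a 2-column TSV of id pairs, validate endpoints, deduplicate.

    For undirected (PPI) lists, each pair is normalized so the endpoint
    with the smaller index comes first; (a,b) and (b,a) collapse to one
    edge and self-pairs are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    src_map = {v: i for i, v in enumerate(valid_src)}
    dst_map = {v: i for i, v in enumerate(valid_dst)}
    edges = []
    for lineno, (s, d) in enumerate(zip(df.iloc[:, 0], df.iloc[:, 1]), start=2):
        if s not in src_map:
            raise ValidationError(f"{path}:{lineno}: unknown endpoint {s!r}")
        if d not in dst_map:
            raise ValidationError(f"{path}:{lineno}: unknown endpoint {d!r}")
        i, j = src_map[s], dst_map[d]
        if undirected:
            if i == j:
                raise ValidationError(f"{path}:{lineno}: self-interaction {s!r}")
            i, j = min(i, j), max(i, j)
        edges.append((i, j))
    if not edges:
        logger.warning("%s: empty edge list", path)
    # dedupe preserving first-seen order
    seen, out = set(), []
    for e in edges:
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


def write_edge_list(edges, src_ids, dst_ids, path, columns=("src", "dst")) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for i, j in edges:
            fh.write(f"{src_ids[i]}\t{dst_ids[j]}\n")


def read_expression(path) -> pd.DataFrame:
    """Read a cell-line x gene expression CSV (first column = cell-line id)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected id column plus gene columns")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        raise ValidationError(f"{path}: duplicate cell-line ids")
    df = df.set_index(id_col)
    if df.isna().any().any():
        bad = [(c, g) for c in df.index for g in df.columns[df.loc[c].isna()]][:5]
        raise ValidationError(f"{path}: NaN expression entries, e.g. {bad}")
    return df


def read_synergy_table(path, drug_ids=None, cell_ids=None) -> list:
    """Read DrugComb-style synergy records; drop records with unknown references.

    Records whose drugs or cell line are not in the supplied id sets, or
    which pair a drug with itself, are dropped with a logged count —
    mirroring intersection filtering of partially overlapping databases.
    """
    df = pd.read_csv(path)
    required = ("drug_a", "drug_b", "cell_line") + SCORE_COLUMNS
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    drug_set = set(drug_ids) if drug_ids is not None else None
    cell_set = set(cell_ids) if cell_ids is not None else None
    records, dropped = [], 0
    for _, row in df.iterrows():
        a, b, c = str(row["drug_a"]), str(row["drug_b"]), str(row["cell_line"])
        if a == b:
            dropped += 1
            continue
        if drug_set is not None and (a not in drug_set or b not in drug_set):
            dropped += 1
            continue
        if cell_set is not None and c not in cell_set:
            dropped += 1
            continue
        scores = {k: float(row[k]) for k in SCORE_COLUMNS}
        records.append(SynergyRecord(a, b, c, scores))
    if dropped:
        logger.warning("%s: dropped %d records with unknown/self references", path, dropped)
    return records


def write_synergy_table(records, path) -> None:
    rows = [
        {"drug_a": r.drug_a, "drug_b": r.drug_b, "cell_line": r.cell_line,
         **{k: repr(r.scores[k]) for k in SCORE_COLUMNS}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", *SCORE_COLUMNS]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------


def build_heterograph(drugs: pd.DataFrame, proteins: pd.DataFrame,
                      dti_edges, ppi_edges, edge_dim: int, seed: int) -> HeteroGraph:
    """Assemble the heterogeneous graph with seeded edge-type features.

    Edge features are one learnable vector per edge type, shared by all
    edges of that type and initialized N(0, 0.01) from `seed`. A graph
    with zero edges of some type is valid (a PPI-free graph is a
    supported ablation) and only triggers a warning.
    """
    rng = np.random.default_rng(seed)
    edge_feat = {
        "dti": rng.normal(0.0, 0.1, size=edge_dim),
        "ppi": rng.normal(0.0, 0.1, size=edge_dim),
    }
    g = HeteroGraph(
        drug_ids=list(drugs["id"]),
        protein_ids=list(proteins["id"]),
        dti_edges=list(dict.fromkeys(tuple(e) for e in dti_edges)),
        ppi_edges=list(dict.fromkeys((min(i, j), max(i, j)) for i, j in ppi_edges)),
        edge_feat=edge_feat,
    )
    g.validate()
    if not g.dti_edges:
        logger.warning("heterograph has no DTI edges")
    if not g.ppi_edges:
        logger.warning("heterograph has no PPI edges")
    return g
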