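"""Seeded generator of a complete synthetic drug-combination dataset.

The generator emits exactly the file formats the readers consume (drug
CSV, protein FASTA, DTI/PPI TSV, expression CSV, synergy CSV) plus a
ground-truth record of the planted mechanism, so end-to-end training and
recovery are testable without any download.

Planted mechanism. Every drug, protein and cell line carries a latent
vector (z_d, z_p, z_c ~ N(0, I)). DTI edges are drawn with probability
proportional to sigmoid(z_d . z_p) thinned to the requested density, PPI
edges form a random geometric graph on the protein latents, and gene
expression is a linear read-out A z_c plus noise. The target synergy
score of pair (i, j) on cell line k is the symmetric, cell-conditioned
bilinear form

    S_T(i,j,k) = alpha * u_i^T diag(z_ck) u_j + beta * (u_i + u_j)^T z_ck + N(0, sigma^2),

where u_d averages the drug's own latent with the mean latent of its DTI
partners. The five non-target score columns are noisy affine transforms
of S_T. Because the truth is itself a cell-conditioned bilinear function
of per-drug vectors, the predictor family contains it (approximately):
failure to recover indicts the implementation, not the generator.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GenConfig
from .exceptions import SynergraphError, ValidationError
from .io import (SCORE_COLUMNS, write_drug_table, write_edge_list, write_fasta,
                 write_synergy_table, SynergyRecord)

logger = logging.getLogger(__name__)

__all__ = ["generate", "planted_oracle", "smiles_library", "GeneratedData"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: affine maps (slope, intercept) from the target score to the other five columns
SCORE_AFFINE = {"css": (1.5, 2.0), "s": (0.8, -1.0), "zip": (0.5, 0.1),
                "bliss": (0.9, 0.0), "hsa": (1.1, 0.5)}

_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "C1CCNCC1",
    "c1ccsc1", "c1ccoc1", "C1CCOC1", "c1cnccn1", "C1CCNC1",
]
_SUBSTITUENTS = [
    "", "C", "CC", "CCC", "O", "N", "Cl", "F", "Br", "C(=O)O", "C(=O)N",
    "OC", "N(C)C", "S", "C#N", "CO", "C(C)C", "CCO",
]
_CHAINS = [
    "CCO", "CCN", "CC(=O)O", "CCCCC", "CC(C)O", "CC(=O)N", "OCCO",
    "NCCN", "CC(C)(C)O", "ClCCCl",
]


def smiles_library() -> list[str]:
    """~100 distinct valid small-molecule SMILES (scaffold x substituent)."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    out, seen = [], set()
    for smi in itertools.chain(
        (s + sub for s, sub in itertools.product(_SCAFFOLDS, _SUBSTITUENTS)), _CHAINS
    ):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            out.append(smi)
    return out


@dataclass
class GeneratedData:
    """Paths and in-memory copies of one generated dataset."""

    paths: dict
    drugs: pd.DataFrame
    proteins: pd.DataFrame
    dti_edges: list
    ppi_edges: list
    expression: pd.DataFrame
    records: list
    ground_truth: dict


def _streams(seed: int, n: int = 8):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate(config: GenConfig, outdir) -> GeneratedData:
    """Generate and write the full dataset; byte-identical for equal configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (rng_drug, rng_prot, rng_dti, rng_ppi, rng_cell, rng_rec, rng_noise, _) = _streams(
        config.seed
    )
    z = config.latent_dim

    # drugs -----------------------------------------------------------------
    lib = smiles_library()
    if config.n_drugs > len(lib):
        raise ValidationError(
            f"n_drugs={config.n_drugs} exceeds the SMILES library ({len(lib)})"
        )
    drug_ids = [f"d{i:03d}" for i in range(config.n_drugs)]
    pick = rng_drug.permutation(len(lib))[: config.n_drugs]
    drugs = pd.DataFrame({"id": drug_ids, "smiles": [lib[i] for i in pick]})
    z_d = rng_drug.normal(size=(config.n_drugs, z))

    # proteins --------------------------------------------------------------
    prot_ids = [f"p{i:03d}" for i in range(config.n_proteins)]
    lengths = rng_prot.integers(50, 301, size=config.n_proteins)
    seqs = ["".join(rng_prot.choice(list(AA20), size=L)) for L in lengths]
    proteins = pd.DataFrame({"id": prot_ids, "sequence": seqs})
    z_p = rng_prot.normal(size=(config.n_proteins, z))

    # DTI: keep prob = density * sigmoid(z_d.z_p) / mean sigmoid ------------
    logits = (z_d @ z_p.T) / np.sqrt(z)
    sig = 1.0 / (1.0 + np.exp(-logits))
    keep_p = np.minimum(1.0, config.dti_density * sig / sig.mean())
    dti_edges = []
    for attempt in range(5):
        mask = rng_dti.random(sig.shape) < keep_p
        dti_edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]
        if dti_edges:
            break
        logger.warning("DTI draw produced no edges; regenerating (attempt %d)", attempt + 1)
    else:
        raise SynergraphError("could not generate any DTI edge in 5 attempts")

    # PPI: random geometric graph on protein latents ------------------------
    diff = z_p[:, None, :] - z_p[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(config.n_proteins, k=1)
    thresh = np.quantile(dist[iu], config.ppi_density)
    ppi_edges = [(int(i), int(j)) for i, j in zip(*iu) if dist[i, j] <= thresh]

    # cell lines ------------------------------------------------------------
    cell_ids = [f"c{i:03d}" for i in range(config.n_cells)]
    z_c = rng_cell.normal(size=(config.n_cells, z))
    A = rng_cell.normal(size=(config.n_genes, z))
    expr = z_c @ A.T + config.expr_noise_sd * rng_cell.normal(
        size=(config.n_cells, config.n_genes)
    )
    expression = pd.DataFrame(
        expr, index=pd.Index(cell_ids, name="cell_line"),
        columns=[f"g{i:04d}" for i in range(config.n_genes)],
    )

    # planted synergy --------------------------------------------------------
    partners: dict[int, list[int]] = {}
    for d, p in dti_edges:
        partners.setdefault(d, []).append(p)
    u = np.array([
        0.5 * (z_d[d] + z_p[partners[d]].mean(axis=0)) if d in partners else z_d[d]
        for d in range(config.n_drugs)
    ])

    pairs = list(itertools.combinations(range(config.n_drugs), 2))
    triples = [(i, j, k) for (i, j) in pairs for k in range(config.n_cells)]
    n_rec = config.n_records
    if n_rec > len(triples):
        logger.warning("n_records=%d exceeds %d possible triples; capping",
                       n_rec, len(triples))
        n_rec = len(triples)
    chosen = rng_rec.choice(len(triples), size=n_rec, replace=False)

    noiseless = np.array([
        config.alpha * float(u[i] * z_c[k] @ u[j])
        + config.beta * float((u[i] + u[j]) @ z_c[k])
        for (i, j, k) in (triples[t] for t in chosen)
    ])
    sigma = config.noise_sd if config.noise_sd is not None else 0.1 * float(noiseless.std())
    target = noiseless + rng_noise.normal(0.0, sigma, size=n_rec) if sigma > 0 else noiseless
    tau = 0.05 * float(noiseless.std())

    records = []
    for row, t in enumerate(chosen):
        i, j, k = triples[t]
        scores = {"loewe": float(target[row])}
        for name, (a, b) in SCORE_AFFINE.items():
            eps = rng_noise.normal(0.0, tau) if tau > 0 else 0.0
            scores[name] = float(a * target[row] + b + eps)
        records.append(SynergyRecord(drug_ids[i], drug_ids[j], cell_ids[k], scores))

    ground_truth = {
        "formula": "S_T(i,j,k) = alpha * u_i^T diag(z_ck) u_j + beta * (u_i+u_j)^T z_ck",
        "alpha": config.alpha,
        "beta": config.beta,
        "noise_sd": float(sigma),
        "score_affine": SCORE_AFFINE,
        "affine_noise_sd": tau,
        "latent_dim": z,
        "z_drug": {d: z_d[idx].tolist() for idx, d in enumerate(drug_ids)},
        "z_prot": {p: z_p[idx].tolist() for idx, p in enumerate(prot_ids)},
        "z_cell": {c: z_c[idx].tolist() for idx, c in enumerate(cell_ids)},
        "u_drug": {d: u[idx].tolist() for idx, d in enumerate(drug_ids)},
    }

    # emit ------------------------------------------------------------------
    paths = {k: outdir / v for k, v in {
        "drugs": "drugs.csv", "proteins": "proteins.fasta", "dti": "dti.tsv",
        "ppi": "ppi.tsv", "expression": "expression.csv", "synergy": "synergy.csv",
        "ground_truth": "ground_truth.json"}.items()}
    write_drug_table(drugs, paths["drugs"])
    write_fasta(proteins, paths["proteins"])
    write_edge_list(dti_edges, drug_ids, prot_ids, paths["dti"], columns=("drug", "protein"))
    write_edge_list(ppi_edges, prot_ids, prot_ids, paths["ppi"],
                    columns=("protein_a", "protein_b"))
    expression.to_csv(paths["expression"], float_format="%.10g")
    write_synergy_table(records, paths["synergy"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)

    return GeneratedData(paths=paths, drugs=drugs, proteins=proteins,
                         dti_edges=dti_edges, ppi_edges=ppi_edges,
                         expression=expression, records=records,
                         ground_truth=ground_truth)


def planted_oracle(ground_truth: dict, drug_a: str, drug_b: str, cell: str) -> float:
    """Noiseless planted synergy score; symmetric in the drug pair."""
    try:
        u_i = np.asarray(ground_truth["u_drug"][drug_a])
        u_j = np.asarray(ground_truth["u_drug"][drug_b])
        z_c = np.asarray(ground_truth["z_cell"][cell])
    except KeyError as exc:
        raise ValidationError(f"unknown id {exc.args[0]!r} in planted oracle") from None
    return float(ground_truth["alpha"] * (u_i * z_c) @ u_j
                 + ground_truth["beta"] * (u_i + u_j) @ z_c)
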