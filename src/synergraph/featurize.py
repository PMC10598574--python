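"""Raw input feature vectors for drugs, proteins and cell lines.

Drugs are encoded as the concatenation fingerprint || one-hot || descriptors:
a 1024-bit circular (Morgan, radius 2) fingerprint, a character-level one-hot
of the canonical SMILES, and eight standardized physicochemical descriptors.
Proteins concatenate a deterministic dipeptide-composition block with a
learnable per-protein embedding drawn N(0,1) at initialization. Cell lines
are per-gene z-scored expression vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .exceptions import ConfigError, FeaturizationError, ValidationError

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

#: 64 common SMILES characters; anything else maps to the trailing UNK slot.
DEFAULT_ALPHABET = list(
    "CNOSPFIBcnospb" "1234567890" "()[]=#@+-/\\%.*:" "HKLiRrelagdtuAGTEZMhXfmVW"
) + ["<UNK>"]

#: N/O atoms carrying at least one hydrogen — counts every O-H/N-H donor,
#: including degenerate molecules like water that the Lipinski pattern skips
_DONOR_SMARTS = Chem.MolFromSmarts("[#7,#8;!H0]")

#: descriptor name -> callable on an RDKit Mol
DESCRIPTOR_FNS = {
    "mol_weight": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "hbd": lambda m: len(m.GetSubstructMatches(_DONOR_SMARTS)),
    "hba": rdMolDescriptors.CalcNumHBA,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

__all__ = [
    "DEFAULT_ALPHABET",
    "DESCRIPTOR_FNS",
    "FeatureBundle",
    "drug_fingerprint",
    "drug_onehot",
    "drug_descriptors",
    "protein_features",
    "cell_features",
    "assemble_bundle",
]


@dataclass
class FeatureBundle:
    """Raw feature matrices, row-aligned with the node/cell-line tables.

    ``drug_blocks`` / ``prot_blocks`` record which column slice of each
    matrix came from which featurizer; the slices partition the columns.
    """

    X_drug: np.ndarray
    X_prot: np.ndarray
    X_cell: np.ndarray
    drug_blocks: dict
    prot_blocks: dict
    cell_ids: list

    def validate(self) -> None:
        for name, (X, blocks) in {
            "drug": (self.X_drug, self.drug_blocks),
            "prot": (self.X_prot, self.prot_blocks),
        }.items():
            cols = sorted((s.start, s.stop) for s in blocks.values())
            pos = 0
            for start, stop in cols:
                if start != pos:
                    raise ValidationError(f"{name} blocks do not partition columns")
                pos = stop
            if pos != X.shape[1]:
                raise ValidationError(f"{name} blocks do not cover all columns")


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES {smiles!r}")
    return mol


def drug_fingerprint(smiles: str, nbits: int = 1024) -> np.ndarray:
    """Morgan radius-2 substructure fingerprint hashed to `nbits` bits."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    fp = gen.GetFingerprint(_mol(smiles))
    return np.array(fp, dtype=np.float64)


def drug_onehot(smiles: str, alphabet=None, max_len: int = 100) -> np.ndarray:
    """Character one-hot of the canonical SMILES, padded/truncated to `max_len`.

    Characters outside the alphabet use its reserved final UNK slot. The
    vector is the row-major flattening of a (max_len, |alphabet|) matrix.
    """
    alphabet = list(alphabet) if alphabet is not None else DEFAULT_ALPHABET
    if not alphabet:
        raise ConfigError("one-hot alphabet is empty")
    if max_len < 1:
        raise ConfigError("one-hot max_len must be >= 1")
    index = {ch: i for i, ch in enumerate(alphabet[:-1])}
    unk = len(alphabet) - 1
    canonical = Chem.MolToSmiles(_mol(smiles)) if smiles else ""
    out = np.zeros((max_len, len(alphabet)))
    if not canonical:
        logger.warning("empty canonical SMILES for %r; zero one-hot", smiles)
        return out.ravel()
    for pos, ch in enumerate(canonical[:max_len]):
        out[pos, index.get(ch, unk)] = 1.0
    return out.ravel()


def drug_descriptors(smiles: str, names=None) -> np.ndarray:
    """Physicochemical descriptor vector (unstandardized; see assemble_bundle)."""
    names = list(names) if names is not None else list(DESCRIPTOR_FNS)
    unknown = [n for n in names if n not in DESCRIPTOR_FNS]
    if unknown:
        raise ConfigError(f"unknown descriptors {unknown}")
    mol = _mol(smiles)
    return np.array([float(DESCRIPTOR_FNS[n](mol)) for n in names])


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Normalized 2-mer composition over the 20-letter alphabet (400 dims).

    2-mers containing 'X' (unknown residue) are skipped. Sequences shorter
    than 2 yield the zero vector.
    """
    counts = np.zeros(400)
    seq = sequence.upper()
    for a, b in zip(seq, seq[1:]):
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia * 20 + ib] += 1.0
    total = counts.sum()
    if total == 0:
        logger.warning("sequence %r has no countable 2-mers; zero block", sequence[:10])
        return counts
    return counts / total


def protein_features(sequence: str, embed_dim: int = 32,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Deterministic dipeptide block concatenated with a learnable N(0,1) block.

    The trailing `embed_dim` entries are the seeded *initial values* of the
    per-protein trainable embedding; training updates them in the model's
    parameter set, not here.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.concatenate([dipeptide_composition(sequence), rng.normal(size=embed_dim)])


def cell_features(expression: pd.DataFrame) -> np.ndarray:
    """Per-gene z-score over the cell-line table; constant genes map to zero."""
    X = expression.to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        rows, cols = np.where(np.isnan(X))
        raise ValidationError(
            f"NaN expression for cell line {expression.index[rows[0]]!r}, "
            f"gene {expression.columns[cols[0]]!r}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant genes standardize to zero
    return (X - mu) / sd


def assemble_bundle(drugs: pd.DataFrame, proteins: pd.DataFrame,
                    expression: pd.DataFrame, config) -> FeatureBundle:
    """Compute all raw features, recording block slices.

    `config` is a RunConfig (or its `featurize` section). With
    ``variant.fps_only`` the drug matrix is restricted to the fingerprint
    block, matching the fingerprint-only ablation.
    """
    feat = getattr(config, "featurize", config)
    fps_only = bool(getattr(getattr(config, "variant", None), "fps_only", False))
    seed = int(getattr(config, "seed", 0))

    errors = []
    fp_rows, oh_rows, desc_rows = [], [], []
    for _, row in drugs.iterrows():
        try:
            fp_rows.append(drug_fingerprint(row["smiles"], feat.fingerprint_nbits))
            if not fps_only:
                oh_rows.append(drug_onehot(row["smiles"], feat.onehot_alphabet, feat.onehot_max_len))
                desc_rows.append(drug_descriptors(row["smiles"], feat.descriptor_names))
        except FeaturizationError as exc:
            errors.append(f"{row['id']}: {exc}")
    if errors:
        raise FeaturizationError("drug featurization failed for: " + "; ".join(errors))

    fp = np.asarray(fp_rows)
    if fps_only:
        X_drug = fp
        drug_blocks = {"fingerprint": slice(0, fp.shape[1])}
    else:
        oh, desc = np.asarray(oh_rows), np.asarray(desc_rows)
        mu, sd = desc.mean(axis=0), desc.std(axis=0)
        sd[sd == 0] = 1.0
        desc = (desc - mu) / sd
        X_drug = np.concatenate([fp, oh, desc], axis=1)
        drug_blocks = {
            "fingerprint": slice(0, fp.shape[1]),
            "onehot": slice(fp.shape[1], fp.shape[1] + oh.shape[1]),
            "descriptors": slice(fp.shape[1] + oh.shape[1], X_drug.shape[1]),
        }

    rng = np.random.default_rng(seed)
    X_prot = np.asarray(
        [protein_features(s, feat.protein_embed_dim, rng) for s in proteins["sequence"]]
    )
    prot_blocks = {
        "sequence": slice(0, 400),
        "embedding": slice(400, 400 + feat.protein_embed_dim),
    }

    if expression.shape[1] != feat.cell_n_genes:
        raise ValidationError(
            f"expression has {expression.shape[1]} genes, config expects {feat.cell_n_genes}"
        )
    bundle = FeatureBundle(
        X_drug=X_drug,
        X_prot=X_prot,
        X_cell=cell_features(expression),
        drug_blocks=drug_blocks,
        prot_blocks=prot_blocks,
        cell_ids=list(expression.index),
    )
    bundle.validate()
    return bundle
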