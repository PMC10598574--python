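"""Drug, protein and cell-line featurizers."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from synergraph import featurize as ft
from synergraph.config import RunConfig
from synergraph.exceptions import ConfigError, FeaturizationError

TOY_SMILES = ["CCO", "c1ccccc1O", "CC(=O)Oc1ccccc1C(=O)O", "CN1CCC[C@H]1c1cccnc1",
              "C1CCNCC1"]


# -- fingerprint --------------------------------------------------------


def test_fingerprint_is_1024_bit_binary():
    fp = ft.drug_fingerprint("CCO")
    assert fp.shape == (1024,)
    assert set(np.unique(fp)) <= {0.0, 1.0}
    np.testing.assert_array_equal(fp, ft.drug_fingerprint("CCO"))


def test_fingerprint_invariant_under_atom_renumbering():
    """The fingerprint depends on the molecule, not the SMILES writing order."""
    rng = np.random.default_rng(0)
    for smi in TOY_SMILES:
        mol = Chem.MolFromSmiles(smi)
        ref = ft.drug_fingerprint(Chem.MolToSmiles(mol))
        n = mol.GetNumAtoms()
        for _ in range(20):
            perm = [int(i) for i in rng.permutation(n)]
            alt = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
            # canonicalization oracle: both spellings canonicalize identically
            assert Chem.MolToSmiles(Chem.MolFromSmiles(alt)) == Chem.MolToSmiles(mol)
            np.testing.assert_array_equal(ft.drug_fingerprint(alt), ref)


def test_fingerprint_unparseable_smiles_errors():
    with pytest.raises(FeaturizationError):
        ft.drug_fingerprint("not_a_molecule((")


# -- one-hot ------------------------------------------------------------


def test_onehot_sets_one_bit_per_character():
    v = ft.drug_onehot("CC", max_len=100)
    assert v.shape == (100 * len(ft.DEFAULT_ALPHABET),)
    assert v.sum() == 2  # canonical "CC" has two characters


def test_onehot_truncates_long_smiles():
    long = "C" * 300
    v = ft.drug_onehot(long, max_len=50)
    assert v.sum() == 50


def test_onehot_unknown_chars_use_unk_slot():
    alphabet = ["C", "<UNK>"]
    v = ft.drug_onehot("CCO", alphabet=alphabet, max_len=10).reshape(10, 2)
    # canonical CCO: two C's then O -> O maps to UNK
    assert v[:3].sum() == 3 and v[2, 1] == 1


def test_onehot_empty_alphabet_is_config_error():
    with pytest.raises(ConfigError):
        ft.drug_onehot("CCO", alphabet=[], max_len=10)


# -- descriptors --------------------------------------------------------


def test_descriptor_vector_has_fixed_length():
    assert ft.drug_descriptors("CCO").shape == (8,)


def test_water_has_hbond_donor():
    names = list(ft.DESCRIPTOR_FNS)
    v = ft.drug_descriptors("O", names)
    assert v[names.index("hbd")] >= 1  # O-H donors counted on the molecular graph


# -- proteins -----------------------------------------------------------


def test_dipeptide_single_kmer_sequence():
    v = ft.dipeptide_composition("AAA")
    assert v[0] == 1.0 and v.sum() == 1.0  # all mass on (A,A)


@pytest.mark.parametrize("seq", ["MKVAC", "ACDEFGHIKLMNPQRSTVWY", "KK"])
def test_dipeptide_normalizes_to_one(seq):
    assert ft.dipeptide_composition(seq).sum() == pytest.approx(1.0)


def test_protein_features_seeded_embedding():
    a = ft.protein_features("MKV", embed_dim=16, seed=5)
    b = ft.protein_features("MKV", embed_dim=16, seed=5)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (416,)


# -- cell lines ---------------------------------------------------------


def test_cell_features_zscore_and_constant_gene_guard():
    df = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [5.0, 5.0, 5.0]},
                      index=["c1", "c2", "c3"])
    X = ft.cell_features(df)
    np.testing.assert_allclose(X[:, 0].mean(), 0, atol=1e-12)
    np.testing.assert_array_equal(X[:, 1], 0)


def test_identical_cell_lines_get_identical_rows():
    df = pd.DataFrame({"g1": [1.0, 1.0, 3.0], "g2": [2.0, 2.0, 0.0]},
                      index=["c1", "c2", "c3"])
    X = ft.cell_features(df)
    np.testing.assert_array_equal(X[0], X[1])


# -- bundle -------------------------------------------------------------


def _inputs(n_genes=12):
    drugs = pd.DataFrame({"id": ["d1", "d2", "d3"],
                          "smiles": ["CCO", "c1ccccc1", "CC(=O)O"]})
    prots = pd.DataFrame({"id": ["p1", "p2"], "sequence": ["MKVAC", "ACDEFG"]})
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(size=(4, n_genes)),
                        index=["c1", "c2", "c3", "c4"],
                        columns=[f"g{i}" for i in range(n_genes)])
    cfg = RunConfig()
    cfg.featurize.cell_n_genes = n_genes
    return drugs, prots, expr, cfg


def test_bundle_block_arithmetic_and_partition():
    drugs, prots, expr, cfg = _inputs()
    b = ft.assemble_bundle(drugs, prots, expr, cfg)
    n_alpha = len(ft.DEFAULT_ALPHABET)
    assert b.X_drug.shape[1] == 1024 + n_alpha * 100 + 8
    b.validate()
    rebuilt = np.concatenate([b.X_drug[:, b.drug_blocks[k]]
                              for k in ("fingerprint", "onehot", "descriptors")], axis=1)
    np.testing.assert_array_equal(rebuilt, b.X_drug)
    # standardized descriptor columns are centered over the table
    np.testing.assert_allclose(b.X_drug[:, b.drug_blocks["descriptors"]].mean(axis=0),
                               0, atol=1e-9)


def test_bundle_fps_only_restricts_to_fingerprint():
    drugs, prots, expr, cfg = _inputs()
    cfg = cfg.with_variant(fps_only=True)
    cfg.featurize.cell_n_genes = expr.shape[1]
    b = ft.assemble_bundle(drugs, prots, expr, cfg)
    assert b.X_drug.shape[1] == 1024
    assert list(b.drug_blocks) == ["fingerprint"]


def test_bundle_rows_follow_table_order():
    drugs, prots, expr, cfg = _inputs()
    b1 = ft.assemble_bundle(drugs, prots, expr, cfg)
    perm = drugs.iloc[[2, 0, 1]].reset_index(drop=True)
    b2 = ft.assemble_bundle(perm, prots, expr, cfg)
    # descriptor standardization sums in table order: equal to rounding only
    np.testing.assert_allclose(b2.X_drug, b1.X_drug[[2, 0, 1]], atol=1e-12)


def test_bundle_reports_offending_drug_id():
    drugs, prots, expr, cfg = _inputs()
    drugs.loc[1, "smiles"] = ")((bad"
    with pytest.raises(FeaturizationError, match="d2"):
        ft.assemble_bundle(drugs, prots, expr, cfg)
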