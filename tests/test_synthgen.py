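"""Synthetic dataset generator: file contract, determinism, planted mechanism."""

import json

import numpy as np
import pytest

from synergraph.config import GenConfig
from synergraph.exceptions import ValidationError
from synergraph.featurize import drug_fingerprint
from synergraph.io import (build_heterograph, read_drug_table, read_edge_list,
                           read_expression, read_fasta, read_synergy_table)
from synergraph.synthgen import generate, planted_oracle, smiles_library


def test_smiles_library_is_large_and_valid():
    lib = smiles_library()
    assert len(lib) >= 100
    for smi in lib[:20]:
        assert drug_fingerprint(smi).shape == (1024,)


def test_emitted_files_pass_all_readers(tiny_data):
    """The generator is the fixture factory: its output must validate."""
    p = tiny_data.paths
    drugs = read_drug_table(p["drugs"])
    prots = read_fasta(p["proteins"])
    dti = read_edge_list(p["dti"], drugs["id"], prots["id"])
    ppi = read_edge_list(p["ppi"], prots["id"], prots["id"], undirected=True)
    expr = read_expression(p["expression"])
    recs = read_synergy_table(p["synergy"], drugs["id"], expr.index)
    g = build_heterograph(drugs, prots, dti, ppi, edge_dim=8, seed=0)
    assert g.n_drugs == 20 and g.n_proteins == 50
    assert expr.shape == (10, 120)
    assert len(recs) == 300
    assert dti == tiny_data.dti_edges and ppi == tiny_data.ppi_edges


def test_same_seed_byte_identical_files(tmp_path):
    cfg = dict(n_drugs=6, n_proteins=12, n_cells=4, n_genes=20, n_records=30, seed=9)
    d1 = generate(GenConfig(**cfg), tmp_path / "a")
    d2 = generate(GenConfig(**cfg), tmp_path / "b")
    for key in d1.paths:
        assert d1.paths[key].read_bytes() == d2.paths[key].read_bytes(), key


def test_noiseless_scores_equal_planted_oracle(tmp_path):
    data = generate(GenConfig(n_drugs=8, n_proteins=15, n_cells=5, n_genes=20,
                              n_records=40, noise_sd=0.0, seed=2), tmp_path)
    for r in data.records:
        assert r.scores["loewe"] == pytest.approx(
            planted_oracle(data.ground_truth, r.drug_a, r.drug_b, r.cell_line), abs=1e-12
        )


def test_oracle_symmetric_and_rejects_unknown_ids(tiny_data):
    gt = tiny_data.ground_truth
    r = tiny_data.records[0]
    assert planted_oracle(gt, r.drug_a, r.drug_b, r.cell_line) == pytest.approx(
        planted_oracle(gt, r.drug_b, r.drug_a, r.cell_line)
    )
    with pytest.raises(ValidationError):
        planted_oracle(gt, "dXXX", r.drug_b, r.cell_line)


def test_cell_latent_localizes_scores(tiny_data):
    """Perturbing one cell's latent changes only that cell's scores."""
    gt = json.loads(json.dumps(tiny_data.ground_truth))
    cells = {r.cell_line for r in tiny_data.records}
    target = sorted(cells)[0]
    gt["z_cell"][target] = [v + 1.0 for v in gt["z_cell"][target]]
    for r in tiny_data.records[:50]:
        before = planted_oracle(tiny_data.ground_truth, r.drug_a, r.drug_b, r.cell_line)
        after = planted_oracle(gt, r.drug_a, r.drug_b, r.cell_line)
        if r.cell_line == target:
            assert before != after
        else:
            assert before == after


def test_dti_density_within_three_standard_errors(tmp_path):
    cfg = GenConfig(n_drugs=40, n_proteins=150, n_cells=3, n_genes=10,
                    n_records=50, dti_density=0.08, seed=4)
    data = generate(cfg, tmp_path)
    n_possible = cfg.n_drugs * cfg.n_proteins
    emp = len(data.dti_edges) / n_possible
    se = np.sqrt(cfg.dti_density * (1 - cfg.dti_density) / n_possible)
    assert abs(emp - cfg.dti_density) <= 3 * se


def test_noise_sd_matches_request(tmp_path):
    sigma = 0.5
    cfg = GenConfig(n_drugs=30, n_proteins=40, n_cells=20, n_genes=10,
                    n_records=6000, noise_sd=sigma, seed=6)
    data = generate(cfg, tmp_path)
    resid = np.array([
        r.scores["loewe"] - planted_oracle(data.ground_truth, r.drug_a, r.drug_b,
                                           r.cell_line)
        for r in data.records
    ])
    assert abs(resid.std() - sigma) / sigma < 0.10


def test_default_counts_match_study_conditions(tmp_path):
    """Default generator shape: 52 drugs, 60 cell lines, 1956 genes, 6 scores."""
    data = generate(GenConfig(n_records=50), tmp_path)
    assert len(data.drugs) == 52
    assert data.expression.shape == (60, 1956)
    assert len(data.proteins) == 200
    assert all(len(r.scores) == 6 for r in data.records)


def test_too_many_drugs_rejected(tmp_path):
    with pytest.raises(ValidationError):
        generate(GenConfig(n_drugs=5000), tmp_path)
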