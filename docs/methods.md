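# Methods

## Problem and model

The package regresses a continuous synergy score for a drug pair on a
cell line. Inputs are five plain-text artifacts: a drug table (id,
SMILES), protein sequences (FASTA), DTI and PPI edge lists (TSV), a
cell-line × gene expression matrix (CSV) and a synergy table with six
score columns (CSS, S, ZIP, Bliss, Loewe, HSA). The six scores are taken
as given; reference-model computation from dose–response surfaces is out
of scope. The regression target defaults to the Loewe score, which is
also the score whose sign defines the binary "synergistic" label
(strictly positive ⇒ synergistic); which score to regress is a free
choice (`train.target_score`).

The network is (a) typed message passing over the drug–protein graph,
(b) a low-rank global attention (LRGA) layer, (c) a two-stage bilinear
predictor. All of it runs on a small reverse-mode autodiff engine over
numpy (`autodiff.py`) whose primitives are finite-difference-checked in
the test suite.

### Interpretive choices in the update rules

The message formulas leave several operators under-determined; the
implementation fixes them as follows, each switchable or at least
isolated in one function:

- *f(h_i, h_j)* is a **learned linear map applied to the neighbour
  state**, one map per edge direction (dp, pd, pp). The alternative
  literal reading — the scalar projection of h_i onto h_j — would make
  messages parameter-free and untrainable.
- The product between an edge feature and a projected neighbour state is
  the **elementwise (Hadamard) product**; shapes only reconcile this way
  when both are width-d vectors.
- Edge features are **one learnable vector per edge type** (one shared
  by all DTI edges, one by all PPI edges), width equal to the hidden
  dimension, initialized N(0, 0.01) from the seed. Per-edge free
  parameters would not generalize and no per-edge data source exists.
  Both DTI directions share one vector.
- The self-loop map ε is a learned linear map per node type,
  **initialized to the identity**, so an isolated node is a fixed point
  at initialization. Aggregation and update are summations; updates are
  synchronous within a layer (all layer-l states depend only on layer
  l−1).

### LRGA

The four heads are learned projections of width k = d/4 by default
(`lrga.split_mode = slice` instead slices contiguous feature blocks, the
other reading of "segmenting" the feature matrix). M₁ and M₂ pass
through a softplus and the normalizer η carries ε_num = 1e-6: for
arbitrary real projections η could vanish or change sign, and the
non-negativity restores a valid attention normalization without touching
the linear-cost claim — the activation is applied before either
association order, so the reassociation identity
(1/η)M₁(M₂ᵀM₃) = (1/η)(M₁M₂ᵀ)M₃ is exact and is asserted against the
quadratic-cost oracle in the tests, together with an instrumented check
that the largest intermediate is max(n×k, k×k) up to n = 10⁴.

Attention is computed over the union of drug and protein nodes (the
"global" in the name); the per-layer output [H ‖ LRGA(H) ‖ GNN(H)] is
re-projected to width d by a learned map with ReLU so layers stack. A
hidden width of 64 with 2 layers is the default; the "64" is a hidden
width, not a stack depth — stacking tens of graph layers at these graph
sizes would oversmooth with no benefit.

### Predictor

Stage 1 is one MLP shared by both drug branches; fusion is
(w·X'_i) ⊙ (w·X'_j) + b with a shared projection w and vector bias b.
Weight sharing plus commutative fusion makes S(i,j,k) = S(j,i,k) exactly
(asserted to 1e-6 over 1000 random triples), which a synergy score must
satisfy. A full outer-product bilinear form (`predictor.fusion = outer`)
and an unshared/concatenation variant (`mlp_only`) exist for comparison;
the concatenation variant deliberately loses the symmetry guarantee. The
first linear layer of each MLP is stored split by input block (drug part
/ cell part) — algebraically identical to one matrix on the
concatenation, but the cell contribution is computed once per cell line
per step instead of once per record.

## Features

- **Drugs**: 1024-bit Morgan fingerprint (radius 2) ‖ character one-hot
  of the canonical SMILES (64-symbol alphabet + UNK, length 100) ‖ eight
  physicochemical descriptors (molecular weight, logP, H-bond donors and
  acceptors, TPSA, rotatable bonds, ring count, heavy atoms), z-scored
  over the drug table. The donor count uses the SMARTS `[#7,#8;!H0]`
  (any N/O with a hydrogen) rather than the Lipinski pattern so that
  degenerate molecules like water count their O–H donors. `fps_only`
  restricts to the fingerprint block.
- **Proteins**: a deterministic dipeptide-composition block (400 dims,
  normalized to sum 1; 2-mers containing X are skipped) concatenated
  with a per-protein **trainable** embedding initialized N(0, 1) from
  the seed. The deterministic block is a plain sequence featurizer — it
  carries composition information only, no evolutionary or contextual
  signal the way a pretrained protein language model would.
- **Cell lines**: per-gene z-scored expression, 1956 genes by default;
  constant genes standardize to zero. Whether to standardize at all is
  an open choice; z-scoring is the package's default and the tests
  depend only on its stated properties.

## Training

Adam (lr 1e-3) with decoupled weight decay 1e-3, batch 256, up to 600
epochs, early stopping on validation MSE (patience 100, best checkpoint
restored), gradient clipping at global norm 5, dropout 0.2 on MLP hidden
layers **and** 0.2 on the predictor inputs (drug embedding and
expression vector — input dropout in the DeepSynergy tradition).
Records are split 6:2:2 at the record level by a seeded shuffle;
leave-drug-out or leave-cell-line-out splitting is not used. The loss is
Smooth L1 by default; the MSE variant exists for ablation and is the one
the gradient clipping mainly protects. One global seed fans out to
per-stage substreams (split / init / batching / dropout / generation),
so toggling one stage does not shift another's randomness; identical
configs reproduce identical metrics bit for bit.

These defaults were chosen for the desk-scale data sizes the package
targets (10²–10³ records): at that scale the dominant failure mode is
memorization of (pair, cell) triples before the factorized structure is
learned, which the combination of dropout, input dropout and weight
decay suppresses. An optional reduce-on-plateau learning-rate decay
exists but is **off by default**: the factorized structure emerges late,
and decaying on an early validation plateau freezes the model in the
memorization regime.

The GAT ablation variant replaces the LRGA block with single-head
masked attention computed on a dense adjacency — adequate for the graph
sizes the harness runs at, and deliberately not a low-rank computation
(that contrast is the point of the variant). The no-PPI variant removes
PPI edges only by default; `variant.no_ppi_drops_dti` additionally drops
the DTI edges for the stricter reading in which the drug–protein network
falls with the PPI network.

## Synthetic data and what the tests show

The generator plants a known mechanism: latents z_d, z_p, z_c ~ N(0, I);
DTI edges with probability ∝ sigmoid(z_d·z_p) thinned to the requested
density; PPI as a random geometric graph on z_p; expression as a linear
readout A·z_c plus noise; and the target score

    S_T(i,j,k) = α · u_iᵀ diag(z_ck) u_j + β · (u_i + u_j)ᵀ z_ck + N(0, σ²)

with u_d the average of a drug's latent and its DTI partners' mean
latent. The five non-target scores are noisy affine transforms of S_T.
Defaults: 52 drugs, 200 proteins, 60 cell lines, 1956 genes, 2000
records, latent dimension 2, α = 0.8, β = 1.2, σ = 10% of the noiseless
score SD.

The mechanism is bilinear in per-drug vectors and conditioned on the
cell line **by design**, so the predictor family contains it
(approximately) and a recovery failure indicts the implementation, not
the generator. The effect sizes deserve a note: the interaction term
carries ~9% of the score variance and the additive (main-effect) term
dominates. Main-effect dominance is what real synergy datasets look
like, and it is also a statistical necessity at this sample size — a
pairwise interaction carrying a large variance share is not
identifiable from ~10³ triples by any member of this model family
(verified by training the predictor on the true latents: it interpolates
the training set and plateaus at the additive ceiling), so a harder
setting would test sample size, not correctness. The latent dimension
(2) keeps the factorization identifiable at the same scale.

What passing tests do show: the pipeline learns a low-rank, symmetric,
cell-conditioned synergy surface from realistic feature encodings
(held-out PCC ≥ 0.9 on the planted mechanism), every architectural
contract holds (symmetry, equivariance, oracle equivalences), and the
training loop can interpolate noiseless data when regularization is
switched off. What they do not show: performance on real DrugComb-scale
data (80k+ records, noisy labels, batch effects, drugs and cell lines
far outside the generator's distribution), the value of the pretrained
protein embeddings the deterministic block stands next to, or anything
about generalization to unseen drugs/cell lines — the splits are
record-level.

## Numerical choices and degenerate inputs

- η guard ε_num = 1e-6; softplus keeps M₁, M₂ ≥ 0, so η > 0 always.
- Constant genes and zero-variance descriptor columns standardize to
  zero (guarded division).
- Empty neighbourhoods contribute zero messages; a graph with no PPI (or
  no DTI) edges is valid and only warns.
- Empty or sub-2-mer protein sequences get a zero composition block with
  a warning; unparseable SMILES abort featurization naming the drug ids.
- The Loewe = 0 boundary labels as non-synergistic (strict inequality).
- Ties in early stopping resolve to the earliest best epoch; the best
  validation checkpoint, not the last epoch, is evaluated.
- Training aborts with a diagnostic if the loss goes non-finite.
- Metrics on constant truth (or constant predictions) report NaN with a
  warning rather than raising.

## Known limitations

- The autodiff engine is deliberately minimal (dense float64, no
  broadcasting beyond numpy semantics, no GPU); graphs beyond ~10⁴ nodes
  or datasets beyond ~10⁵ records would need a real tensor framework.
- The GAT variant materializes a dense n×n mask and is only meant for
  small graphs.
- Protein sequence information enters only through dipeptide composition
  and a trainable embedding; homology and structure are invisible.
- Record-level splits measure interpolation over known drugs and cell
  lines, not extrapolation to new chemistry or biology.
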