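# Methods

## Model

A (peptide, protein) pair is a two-node graph: node 0 holds the peptide's
pooled sequence embedding, node 1 the protein's, with the bidirectional
edge index [[0,1],[1,0]] and no stored self-loops.  Self-loops enter only
inside the graph-convolution operator, whose propagation matrix is
D̂^(-1/2)(A+I)D̂^(-1/2); keeping them out of the stored edge list lets the
graph object and the operator each match their usual conventions.

The stack is GCNConv(D→64) → GCNConv(64→64) → GINConv(64→64) →
GINConv(64→32) → global add pooling → dropout → linear → sigmoid.  Each
GCN layer applies the propagation, a linear map with bias, normalization,
ReLU, and 20 % dropout during training.  Each GIN layer aggregates
(1+ε)·h_v + Σ_{u∈N(v)} h_u over the stored (self-loop-free) edges and
maps it through a two-layer MLP (linear → ReLU → linear, hidden width =
output width); ε defaults to 0.  The loss is binary cross-entropy
evaluated in logit space (softplus form), so saturated logits stay
finite.

A structural consequence worth stating explicitly: on the two-node graph
with self-loops, propagation maps both rows to the same vector
0.5(h₀+h₁)W, so the model output is a function of the *sum* of the two
node embeddings and is exactly invariant under swapping the peptide and
protein rows.  The test suite asserts this invariance numerically.

### Normalization axis

After propagation the two node rows are identical, so instance
normalization applied per graph-channel across nodes would subtract each
row from itself and zero every feature.  The default therefore
standardizes each node's feature vector across channels (with learnable
affine parameters); the cross-node variant is retained as an
epsilon-guarded option (`norm_mode="per_graph_channel"`) for ablation but
is degenerate on pair graphs and not used by default.

### Implementation

The forward pass, backpropagation and the Adam loop are written in NumPy.
The architecture is small (two dense propagation steps on 2-node graphs,
two small MLPs, a linear head) and a hand-derived backward pass is both
fast at this scale and fully deterministic under a fixed seed; a
finite-difference gradient check and an independent dense-matrix forward
reference guard it in the tests.

## Training protocol

Adam with learning rate 1e-3 and weight decay 5e-4 (L2 added to the
gradient), batch size 64, at most 200 epochs, seed 1234.  Each
cross-validation fold carves a stratified 10 % validation set out of its
training portion; early stopping monitors validation AUC (threshold-free)
with patience 10 and restores the best-validation parameters.  The
decision threshold is the smallest candidate (midpoints of consecutive
distinct validation scores plus {0,1}) maximizing validation F1, then
frozen for test evaluation.  Z-score statistics (per feature dimension,
population standard deviation, ε = 1e-8) are fit on the training
entities of the fold only and shared between peptides and proteins, which
occupy one node-feature space.  No test-fold information reaches
normalization, early stopping or threshold choice.

## Metrics

ACC and F1 follow the confusion counts of the inclusive rule
prob ≥ threshold, with F1 = 0 when TP = 0 amid errors.  AUC is the
Mann–Whitney rank statistic; AUPR is the step-wise integral of precision
over recall with score ties handled as blocks (scikit-learn's
implementations, cross-checked in the tests against O(n²) and
threshold-sweep brute-force oracles).  Methods evaluated on the same
folds are compared with a paired two-sided t-test on per-fold accuracies;
zero-variance differences degenerate to p = 1 (zero mean) or p = 0
(non-zero mean, flagged).

## Dataset construction from structures

Residues on different chains interact when their Cα–Cα distance is
strictly below 5 Å; when either residue lacks a Cα the nearest
inter-atomic distance across all atom pairs is used; a residue with no
usable coordinates is non-binding by convention.  The peptide chain is
the shortest chain of ≤ 50 observed residues (configurable) and every
other chain is examined independently.  Chain sequences are read from
coordinate records (SEQRES ignored) because contacts are defined on
coordinates.  Pairs where either sequence exceeds 20 % non-standard
residues (outside the canonical 20; B, Z, X, U, O, J accepted but counted
non-standard — the list is configurable) are dropped, with "exceeds"
strict, so exactly 20 % is retained.  Negatives are uniform draws without
replacement from the non-positive (peptide, protein) combinations, one
per positive; only exact known positives are excluded.  No resolution
filter is applied: no numeric cutoff is defensible from first principles
here, and the coordinate-completeness rule already covers the degenerate
cases.

## Cold-start splits

Peptides and proteins are clustered independently by a CD-HIT-style
greedy pass: descending length order (ties by id), each sequence joins
the first cluster whose representative it matches at ≥ threshold, else
founds one.  Identity is the maximal number of identically aligned
positions of a global alignment (match +1, mismatch 0, zero gap penalty)
divided by the shorter length — CD-HIT's denominator — dropping CD-HIT's
k-mer prefilter and banded heuristics, which only affect speed and
tie-breaking, not the contract.  Splits assign whole clusters to train or
test: the constrained entity type's clusters are shuffled with the seed
and accumulated into test until the requested pair fraction (default
0.2) is reached; under `novel_pairs` both types are constrained and
straddling pairs are dropped and counted.

## Synthetic generators

`gen_interaction_data` draws peptide and protein embeddings i.i.d.
standard normal and labels each pair through a planted rank-r subspace U
(orthonormal, default r = 2): score = ‖Uᵀ(p+q)/2‖², plus Gaussian noise
of 0.1 score-standard-deviations, thresholded at the quantile matching
the requested positive fraction (default 0.5, the balanced-benchmark
convention).  The quadratic form of the pair *mean* is deliberate.  The
architecture's output is a function of p+q only (see above), and for
independent entities a purely cross-term bilinear label p′ᵀMq has a
distribution-free Bayes ceiling of AUC 5/6 from the sum — no training
could pass a 0.9 learnability bar.  The pair-mean form keeps the cross
term pᵀUUᵀq inside the score while remaining recoverable from the sum,
so the generated problem probes learnability rather than an
impossibility.  Defaults: 50 peptides × 40 proteins crossed into 2 000
pairs, dim 64 — large enough for a stable AUC estimate, small enough for
a desk-scale run.  What the generator does not emulate: real language-
model embedding geometry (anisotropy, length correlation), homology
between entities, and label noise structure; passing tests show the
pipeline learns a planted low-rank interaction from its inputs, not that
any particular real-data accuracy will be reached.

`gen_toy_structures` realizes a contact plan as PDB files on a widely
spaced grid (50 Å between residues, chains 500 Å apart) so each planned
contact is the only sub-threshold pair; plans cover the exact-5.0 Å
boundary, missing-Cα (nearest-atom) cases, unresolved residues (written
with no coordinate records, present only in the truth table), altloc
resolution, and peptides crossing the 20 % non-standard filter.

`gen_sequence_families` mutates family founders from a common ancestor;
the per-position substitution rate solves (1−μ)² = target identity under
the ungapped model (two members are independent mutants of one founder).
Gap-tolerant measured identity is bounded below by this target and, for
unrelated sequences, floors at the random-alignment background of the
20-letter alphabet.

`hash_embed` is the deterministic stand-in for the residue-level
language-model backend: each row is a reproducible Gaussian vector keyed
by the (2w+1)-mer context (w = 1) and the seed, satisfying the same
sequence → L × D contract as the optional pre-trained adapter, so every
downstream stage is testable without model weights.

## Numerical choices and limitations

- Normalized adjacency computed as A_ij/√(d_i d_j) in one division, so
  the pair-graph entries are exactly 0.5.
- Mean pooling short-circuits constant matrices to return the row
  bit-exactly.
- Distance comparisons are strict (<); a pair at exactly 5.0 Å is
  non-binding.
- Weight initialization is uniform fan-in with the run seed; all
  randomness (init, shuffling, dropout, sampling) flows from explicit
  generators, so equal seeds give bit-identical runs.
- The t-test is paired, reflecting comparison on shared folds.
- Known limitations: pair-level prediction only (no residue-level binding
  sites); clustering is O(n·clusters) alignments and not suited to very
  large sequence sets; the dataset builder reads PDB, not mmCIF; the
  pair-symmetry property means the model cannot distinguish which member
  of a pair is the peptide — a structural property of the two-node
  sum-based design.
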