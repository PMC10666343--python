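# Methods

This note documents the models and procedures `ncbind` implements, the
parameters that matter, the choices made where the published description
of this architecture family leaves the design open, and what the synthetic
data can and cannot establish.

## Problem and data model

The task is binary classification of short peptides (8–15 canonical
residues) into binders and non-binders of a non-classical HLA class I
allele.  Datasets arrive as positive and negative FASTA files; the
benchmark layout has five allele-specific datasets with 142, 632, 2633,
751 and 812 positives and either equal negatives (balanced) or ten times
as many (imbalanced).  Peptides are validated against the 20-letter
alphabet; ambiguous codes (B, J, O, U, X, Z) are rejected because every
encoding table covers exactly 20 residues.  No deduplication is performed:
whether duplicates within or across datasets should be removed is a
dataset-curation question the package does not decide for the user.

## Encodings

Three per-residue channels, stacked position-major into an `L_max × C`
matrix:

* **EIIP**: table lookup of the electron-ion interaction pseudopotential,
  stored to the five decimals of the reference table used throughout this
  package.  That table is authoritative here even where other published
  EIIP tables differ (it assigns, for instance, 0.00000 to both leucine
  and isoleucine and 0.37100 to both alanine and lysine — so EIIP alone
  is not injective).
* **INM**: table lookup of a fixed bijection residue → {1..20}
  (alphabetical by full amino-acid name).  Losslessly invertible.
* **AAAF**: `f(s_j) = (1/j) Σ_{t≤j} [s_t = s_j]`.  Prefix-dependent by
  construction: element 1 is always 1, all elements lie in (0, 1], and an
  all-distinct peptide yields exactly (1, 1/2, …, 1/n).

Padding: sequences are post-padded to `L_max = 15` (the benchmark's
maximum length) with 0 in every channel; 0 is reserved in the INM
vocabulary for padding so the embedding distinguishes pad from residue 1.
The padding scheme of the original description is unstated; post-padding
with a reserved symbol is this package's convention.  AAAF is always
computed on the unpadded peptide.  Encoders themselves accept any n ≥ 1
(the worked example is a 6-mer); the 8–15 bounds apply to dataset
assembly.

## Network

Input `L_max × C` → embedding front-end → two parallel branches →
concatenation → dense head:

* **Embedding of mixed channels.** How continuous channels pass "through
  an embedding layer" is under-specified in the family of models this
  implements.  Decision: the INM channel uses a learned lookup table
  (vocabulary {0..20}, width `embedding_dim`); each continuous channel
  (EIIP, AAAF) uses a learned affine map `v ↦ v·w + b` into the same
  width; the streams are summed position-wise, yielding one embedded
  sequence as in the single-stream flowchart.
* **Branches.** `Conv1D` with kernel 10 (branch 1) and 8 (branch 2),
  valid padding (with `L_max=15` the branch lengths before pooling are 6
  and 8 — the stated kernel sizes only make sense un-padded), ReLU, max
  pooling with window 2, batch normalisation, dropout at rate 0.5, then a
  bidirectional LSTM.  The Bi-LSTM is summarised by the concatenated
  final hidden states of the two directions, a fixed-width vector that
  concatenates cleanly across branches of different lengths.
* **Head.** Dense(ReLU) then Dense(1) with sigmoid
  `σ(x) = (1+e^{-x})^{-1}`.  Whether both dense layers are ReLU is
  unstated; ReLU-then-sigmoid is the decided reading.  Classification
  uses the strict rule: binder iff probability > threshold (default 0.5,
  so a probability of exactly 0.5 is a non-binder).

Hyper-parameter defaults not fixed by the architecture description (they
come from an unavailable supplement) are this package's choices, all
exposed in `ModelConfig`: `embedding_dim=32`, `conv_filters=64` per
branch, `lstm_units=64` per direction, `dense_units=64`, Adam with
learning rate 1e-3, `batch_size=32`, `epochs=100` with early stopping on
a stratified 10 % validation split (patience 10, best weights restored).
Weight initialisation is Glorot uniform (embedding table: uniform ±0.05;
LSTM forget-gate bias 1).

### Implementation

The network is written directly in NumPy (float64) with hand-coded
backpropagation for every layer, including full backpropagation-through-
time for the Bi-LSTM and the batch-statistics gradient for batch
normalisation.  The test suite verifies all analytic gradients against
central finite differences.  Consequences: training is single-threaded
and bit-for-bit reproducible under `ModelConfig.seed` (which governs
initialisation, shuffling, the validation split and dropout masks) — the
determinism tests assert exact equality, not a tolerance — and model
sizes are deliberately modest; this is a CPU-scale reimplementation, not
a GPU training harness.

Numerical choices: sigmoid and binary cross-entropy are computed in their
numerically stable logit forms (no overflow at |x| up to 1e4); a
non-finite loss raises a divergence error naming the epoch; `epochs=0` is
legal and leaves the initialised model usable (batch-norm running
statistics start at mean 0 / variance 1).

### Ablation variants

`build_variant` provides the six-architecture taxonomy used for module
comparisons: `cnn_only`, `bilstm_only`, `cnn_then_bilstm_series` (one
conv branch feeding a Bi-LSTM), `cnn_parallel`, `bilstm_parallel`, and
`full` (identical to `build_model`).  Non-recurrent variants flatten the
pooled convolution output before the dense head.  Channel ablations
(any non-empty subset of EIIP/INM/AAAF) are selected through
`ModelConfig.channels`; channel order is fixed as (EIIP, INM, AAAF).

## Evaluation

`SN = TP/(TP+FN)`, `SP = TN/(TN+FP)`, `ACC = (TP+TN)/N`,
`MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN))`.  Conventions for
degenerate counts: a zero factor under the MCC root reports MCC = 0 with
an explicit flag; SN or SP with an empty class is NaN with a flag rather
than a silent 0.  The ROC curve is built from TPR/FPR at every distinct
score threshold, anchored at (0,0) and (1,1); AUC is its trapezoidal
integral, which the tests verify equals the Mann–Whitney rank statistic
(ties at ½) to 1e-12.

Protocols:

* **k-fold cross-validation** (default k=5): folds are *stratified* —
  with only 142 positives in the smallest dataset, unstratified folds can
  degenerate — shuffled under the protocol seed.  Per-fold metrics are
  macro-averaged for the headline numbers; the pooled out-of-fold scores
  are also kept, since pooling is the lower-variance estimate of the
  same quantity and which of the two a published table used is often
  unstated.  Each fold's model trains from a fresh seed derived from the
  protocol seed.
* **Repeated hold-out** (default 10 repeats × 10 % test): plain random
  shuffles, as the imbalanced-category protocol describes; a split that
  misses a class is redrawn with the next sub-seed and the redraw is
  recorded.
* **Method comparison**: two-sample Welch t-test, two-sided, on
  per-repetition metric values.  Welch (unpaired) because no pairing
  exists between this implementation's runs and an external method's
  published runs; two constant equal samples report p = 1.

## Entropy analysis

`Z` is 20 × n with `z_{ij}` the probability of residue i at position j,
estimated by counting.  Variable lengths are handled by left-aligned,
1-based positions with column j conditioned on the peptides of length ≥ j
— conditioning avoids inventing a 21st "absent" symbol, at the cost that
deep columns rest on fewer peptides (the per-column coverage is reported).
`AP^i = Σ_j −z_{ij} log z_{ij}` and `PP^j = Σ_i −z_{ij} log z_{ij}` with
0·log 0 = 0; logarithms are base 2 (bits) throughout, so PP ranges over
[0, log₂20 ≈ 4.32].  A column with zero coverage is NaN (undefined), not
0 — 0 would mean a perfectly conserved position.  Reports cover the
positive set, the negative set and their union (POS / NEG / SUM), so
every reading of "computed over the balanced dataset" is available.  Note
one subtlety the example scripts demonstrate: under this conditional Z an
anchor at position j depresses AP for *every* residue (the anchor residue
because z ≈ 1 there, the rest because z ≈ 0), so AP comparisons are most
meaningful between groups, not between residues.

## Synthetic data

The generator emulates the statistical shape of the benchmark, not its
immunology: i.i.d. residues from a background distribution (uniform by
default, so the entropy limits above are exact; a natural-abundance
profile is available but not default) at lengths uniform on 8–15, with
positives carrying anchor motifs `(position, residue, strength)` applied
with probability `strength` to peptides long enough to have the position
(length-conditional semantics, matching the conditional Z).  The default
anchor is leucine at position 9 with strength 0.9 — position 9 because
that is where the benchmark's own positional-entropy analysis finds the
anchor signal, strength 0.9 because a strong-but-probabilistic anchor
reproduces the "high but imperfect separability" regime of the real
datasets.  `benchmark_shape` fixes the five positive counts and the 1:1
or 1:10 ratio.

What passing tests on this data do and do not show: they establish that
the pipeline recovers plantable positional signal up to nearly the Bayes
optimum (with the 0.9-strength position-9 anchor and uniform lengths
8–15, an 8-mer positive carries no anchor, capping even the optimal AUC
near 0.92), that AUC responds monotonically to signal strength, and that
a signal-free dataset yields chance-level AUC (a leakage check).  They do
not establish real-world accuracy: real binder sets have correlated
residues, multiple anchors, biased backgrounds and label noise, none of
which the generator models.

## Problem sizes in the checked workflows

The test suite trains at desk scale by choice: signal-recovery checks use
1,000 + 1,000 peptides with 5-fold cross-validation or a 30 % hold-out
(epochs 40, patience 8); the ablation harness uses 250 + 250 peptides at
8 epochs; protocol-invariant checks run with `epochs=0` models, which
exercise the split machinery without training cost.  The default
`ModelConfig` is sized for the real benchmark datasets (hundreds to
thousands of peptides) on a single CPU.

## Known limitations

* No GPU path and no minibatch parallelism; wall-clock scales linearly
  with data size and epochs.
* The EIIP table's collisions (I/L, A/K, C/S) make the EIIP channel
  non-injective; INM carries the full residue identity.
* Batch-norm statistics come from training batches; very small batch
  sizes give noisy statistics (batch_size ≥ 8 recommended).
* The entropy module reports no significance tests for POS/NEG entropy
  differences; it is descriptive, as is conventional for this analysis.
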