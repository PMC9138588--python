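# Methods

This note records the modelling assumptions, the numerical and design
choices that were genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Problem setting

A DTI benchmark is a bipartite graph: drugs, protein targets, and a
set of experimentally confirmed interacting pairs. Only positives are
curated, so supervised learning requires constructing negatives; the
standard practice adopted here samples them uniformly without
replacement from the cross-product minus the positives, matched in
size to the positive set. Sampling is done once per run with a seeded
PCG64 permutation of enumerated candidate cells, so the draw is
reproducible across platforms; a per-fold resampling flag exists for
sensitivity analysis. The classifier therefore answers: "does this
pair look more like a known interaction than like a random unlabeled
pair?" — a noisy proxy, since some unlabeled pairs are true
interactions (this is also the irreducible-noise mechanism in the
synthetic generator, below).

## Descriptors

**PSSM.** The PSI-BLAST ASCII PSSM carries two 20-column blocks per
residue; the log-odds block is used and the weighted-percentage block
discarded, because log-odds are the standard "evolutionary
information" encoding and the percentages are a redundant rescaling.
Parsing is strict (44 whitespace tokens per row, positional indices
checked) and errors name the offending row.

**Fixed-size protein matrix.** CNN input must be fixed-size but
protein length H varies; the profile is condensed to Θᵀ Θ / H. This
choice is: length-invariant (it is a mean over residues of per-residue
outer products, so it is also invariant to residue permutation —
sequence *order* information is deliberately discarded), symmetric,
and 20×20, a natural single-channel image. Pad/crop to a fixed length
was the considered alternative; it keeps order information but makes
the input dimension depend on an arbitrary length cap and mixes zero
padding with real scores, so the cross-product form was preferred.

**Fingerprint codec.** Base64 text decodes to a 4-byte big-endian bit
count (which must equal 881, the PubChem substructure key length)
followed by MSB-first packed bits; pad bits must be zero. The codec is
round-trip exact and is additionally checked against an independent
byte-walking decoder in the tests.

**Fusion.** Protein features and fingerprint bits are concatenated
*after* CNN extraction (late fusion). Fusing before the CNN is
ill-defined for heterogeneous 1-D + 2-D data under 2-D convolution; an
"early" mode is nevertheless available (protein matrix and fingerprint
as two zero-padded 30×30 channels) for comparison. Late fusion is the
default and the tested configuration.

**2DPCA ablation descriptor.** As an alternative protein descriptor
the image-covariance eigenbasis G = (1/n) Σ (A_i − Ā)ᵀ(A_i − Ā) is
computed on the training fold, each sample is projected onto the k
leading eigenvectors (default k = 6, giving 120 features,
commensurate with the CNN's 128), and the projection is flattened.
Eigenvector signs are fixed (largest-magnitude component positive) so
results are independent of sample ordering.

## CNN feature extractor

Architecture (config-driven; default chosen as the smallest stack that
exercises convolution, subsampling, and dense mapping): 20×20 input →
conv 3×3 ×8 → mean-pool 2×2 → conv 3×3 ×16 → mean-pool 2×2 → dense 128
(the feature layer Γ) → dense 2. Hidden activation is ReLU, the head
is softmax; pooling is mean by default (max available) — mean keeps
the objective smooth, and odd trailing rows/columns are dropped by the
non-overlapping window. The loss is mean cross-entropy plus
(θ/2) Σ W² over kernels and dense weights (biases unpenalized);
optimization is full-batch gradient descent with fixed learning rate
ε. Defaults: θ = 1e-4, ε = 0.05, 15 epochs — the planted problems are
easy, and longer schedules only add runtime. Initialization is seeded
uniform(−0.1, 0.1) with zero biases; training is deterministic given
seed and data order, and a non-finite loss raises an error naming the
epoch. All gradients are analytic and are verified against central
finite differences (relative error < 1e-5) for every layer type.

Per cross-validation fold the CNN is trained on the training fold only
and then frozen for feature extraction of both folds; the trainer
callback never receives test-fold labels.

## ELM classifier

Hidden weights and offsets are drawn once from seeded uniform(−1, 1)
and never trained; output weights are the minimum-norm least-squares
solution of S V = P (rank-revealing solve, relative singular-value
cutoff 1e-12), with targets one-hot encoded and the decision score the
positive-minus-negative output margin (ties → negative). The library
default width is N = min(1000, 10 L).

Two pipeline-level conditioning choices matter in practice:

- **Feature scaling.** Fused features are z-scored with training-fold
  statistics and divided by √d. Without the √d factor the hidden
  pre-activations have sd ≈ √(d/3) ≈ 18 at d ≈ 1000 and the sigmoid
  saturates into a random-sign hash, which measurably degrades
  ranking quality on the planted data (mean AUC ≈ 0.94 vs ≈ 0.99).
- **Width.** The pipeline passes N = min(500, L/2). At N ≈ L the
  least-squares solve interpolates the training set exactly and test
  AUC collapses (the classical over-fitting spike at the
  interpolation threshold); keeping N well below L leaves the solve
  over-determined and stable.

## Evaluation

Metrics are the confusion-matrix five (accuracy, sensitivity,
specificity, precision, MCC) plus AUC. A metric with a zero
denominator on some fold is flagged undefined (None) and skipped in
aggregation rather than poisoning the report. The ROC sweep groups
tied scores into a single threshold step and integrates by trapezoid,
which equals the Mann–Whitney statistic with half credit for ties (and
is asserted against that pairwise oracle, and against an independent
library implementation, in the tests).

Folds: seeded shuffle, sizes ⌊n/5⌋ with the first n mod 5 folds one
larger; splitting is over pairs, not over drugs or proteins
(cold-start evaluation is out of scope). Stratified splitting
(round-robin within each shuffled class) is available behind a flag
but off by default, matching the plain "roughly equal subsets"
protocol. Aggregation is mean ± *sample* standard deviation (n−1):
the n−1 convention reproduces the published benchmark deviation rows
from their per-fold cells (e.g. the enzyme accuracy row 94.19 ± 0.41;
the population sd gives 0.37), which pins down the convention those
tables used. Three published std cells (enzyme AUC, GPCR accuracy,
nuclear-receptor sensitivity) differ from their recomputed values by
0.01 after rounding; the test suite lists exactly those three rather
than hiding them.

Published headline accuracies/AUCs themselves are *not* reproduced
here: they require the deposited benchmark interaction lists,
SwissProt-backed PSI-BLAST profiles, and unreported network
hyper-parameters. What is reproduced is everything arithmetic about
the published tables, plus full-pipeline signal recovery on synthetic
data (below).

## Synthetic generator

The generator emulates the three input families in their exact
external formats (pair list, Base64 fingerprint table, ASCII PSSM
directory — everything round-trips through the package's own
parsers). The planted construction gives every drug and target a
latent class bit (exactly balanced); a pair enters the positive set
with weight 1 + s if the bits agree and 1 − s otherwise
(s = signal_strength), and the bits shift the observable features:
bit-1 drugs have fingerprint density 0.2 + 0.3 s (vs 0.2), bit-1
targets have PSSM log-odds mean +2 s (vs 0, sd 3, integers clipped to
[−10, 12], lengths uniform on [80, 200]). The label is thus an
agreement (XOR-like) function of two feature groups — deliberately not
linearly separable from either modality alone, so recovery requires
both descriptors and a nonlinear classifier.

Default study conditions: 32 drugs × 32 targets, 500 positives + 500
sampled negatives. The universe size is chosen so that at s = 1 the
~512 agreeing pairs are almost exhausted by the 500 positives, leaving
a negative sample that is nearly purely disagreeing pairs; the
remaining dozen agreeing negatives put the Bayes AUC ceiling at
≈ 0.989, and the pipeline reaches ≈ 0.988 (five-fold mean over seeds
0–4). At s = 0 features and labels are independent and the pipeline
sits at chance. These problem sizes keep a full five-seed recovery
experiment at about a minute on one CPU.

What passing these tests shows: the pipeline recovers a strong planted
low-rank association signal end-to-end, with no leakage, from inputs
in the real file formats. What it does not show: performance on
curated data — real fingerprints have correlated substructure bits,
real PSSMs have amino-acid-specific column structure and homology
between targets, and real interaction matrices are far sparser and
not generated by two latent classes.

## Candidate ranking

For prospective screening the model is trained on all positives plus
one sampled negative set, every non-positive pair is scored, and the
top k are reported (ties broken lexicographically). On planted data
with all but one agreeing pair used as positives, the single held-out
signal-carrying pair is recovered at rank 1 in 5/5 seeds — even though
it is almost surely present in the sampled negative training set,
the under-parameterized ELM cannot memorize the mislabeling.

## Known limitations

- No real-data ingestion beyond the three file formats: no KEGG /
  DrugBank / PubChem lookups, no PSI-BLAST invocation, no SMILES.
- Negative sampling assumes unlabeled = non-interacting; prospective
  ranking scores are therefore relative, not calibrated probabilities.
- The CNN optimizer is plain full-batch gradient descent (no
  momentum/Adam, no mini-batching); adequate at these problem sizes,
  slow beyond them.
- Pair-level cross-validation measures in-matrix generalization only;
  cold-start (new drug / new target) performance is untested.
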