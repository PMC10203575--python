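# Methods

This note records what `tfbsnet` computes, the modelling assumptions behind
each component, the default parameter values and why they were chosen, and the
numerical decisions that matter for reproducing results.

## Problem setting

Given a set of DNA sequences labelled as bound / not bound by a transcription
factor, the package (1) trains a convolutional classifier to predict binding
probability from sequence alone, and (2) interrogates the trained model to
recover *where* and *through which subsequences* the predicted binding signal
arises. All sequence inputs are fixed-length strings over `A/C/G/T/N`,
one-hot encoded as `(L, 4)` arrays with `N` encoded as an all-zero row, so that
masking a base and deleting its information content are the same operation.

## Data construction

Two data paths produce the same artifact shape (FASTA + a TSV label table):

* **Genomic** (`make-data`): peak summits or intervals from BED/narrowPeak are
  extended by a flank of 250 bp on each side (500 bp windows; narrowPeak
  summits are used when present, otherwise interval midpoints). Negatives are
  random genomic windows of the same length, rejected if they overlap any
  positive (or an extra exclusion set, via an interval tree), lie outside a
  chromosome, or contain more than 10 % `N`. Sampling aborts with an explicit
  error rather than silently under-delivering. Train/test splitting is a
  seeded 80/20 shuffle.
* **Synthetic** (`synth`): i.i.d. background sequences at a configurable GC
  content, with a known motif planted (by replacement) at a uniformly random
  offset in each positive. The generator emits a ground-truth table (sample
  id, plant offset, planted subsequence), which is what makes end-to-end
  validation of the interpretability stack possible: each method's output can
  be compared against the exact planted coordinates.

The synthetic benchmark emulates the *statistical shape* of the genomic task —
balanced classes, fixed-length windows, a short informative subsequence in an
uninformative context — but not genomic realities such as repeat structure,
GC heterogeneity, chromatin context, or degenerate motif instances (a PWM can
be planted instead of a literal k-mer to soften the last point). Defaults are
2000 positives + 2000 negatives of 500 bp, GC 0.5, motif `GCACGTGC` (an
E-box-like palindrome). This problem size is the package's own choice for its
reference benchmark: it is large enough that a small model generalises
(held-out AUC > 0.95) and that per-position statistics over 100 test
sequences are stable, while staying comfortable to run on a laptop CPU.

## Classifier

`DenseNetClassifier` is a densely connected 1-D CNN:

* **Stem**: two `Conv(64, k=3)` layers (each BN + ReLU), then average pooling.
* **Four dense blocks** of (6, 12, 24, 16) layers with growth rate 32. Each
  layer is pre-activation bottleneck style — BN → ReLU → `Conv(4·growth, k=1)`
  → BN → ReLU → `Conv(growth, k=3)` — and its output is concatenated onto the
  running feature map, so every layer sees all earlier features.
* **Transitions** between blocks: BN → ReLU → `Conv(k=1)` halving the channel
  count, then average pooling (stride 2).
* **Head**: BN → ReLU → flatten → a single dense logit → sigmoid.

Training is Adam (learning rate 1e-3) on binary cross-entropy, batch size 64,
at most 80 epochs, with a 10 % validation split and early stopping (patience
5) that restores the best-validation-loss weights. He initialisation is used
for convolutions. The estimator follows the scikit-learn protocol
(`get_params`/`set_params`/`fit`/`predict`/`predict_proba`, fitted attributes
with trailing underscores, `clone`-compatible), and `fit` is deterministic
given `random_state`.

The network is implemented directly in NumPy (im2col convolutions, manual
backpropagation) rather than on a deep-learning framework; this keeps the
package dependency-light and every gradient inspectable. Forward/backward
correctness is pinned by finite-difference tests. Parameters and activations
are float32; the final sigmoid and all attribution arithmetic are float64.

## Interpretability

All methods operate on any model exposing `input_length_`,
`predict_scores(X)` and `probability_gradients(X)`; tests exploit this with
closed-form additive scorers as oracles.

* **Contribution scores** are integrated gradients of the predicted
  probability along the straight line from a reference to the sequence,
  averaged over 10 dinucleotide-shuffled references. Dinucleotide shuffling
  (exact Altschul–Erickson Eulerian-path shuffle, preserving the full
  dinucleotide count table — property-tested) is the reference choice because
  it destroys motifs while keeping low-order composition. The path integral
  uses 32-node Gauss–Legendre quadrature: with a sigmoid output the integrand
  is smooth but sharply curved, and Gauss–Legendre at 32 nodes keeps the
  completeness residual `|Σ scores − (p(seq) − mean p(ref))|` within
  `0.1·|p(seq) − mean p(ref)| + 0.01` with a wide margin, where a 16-point
  midpoint rule does not. This is an accuracy choice, not a tolerance choice.
* **Tiling deletion** slides a 10-bp window in steps of 1, masks it to `N`
  (zero rows) and records `p(wild type) − p(masked)`.
* **Saturation mutagenesis** evaluates `p(mutant) − p(wild type)` for every
  single-base substitution (reference cells are 0 by construction).
* **Seqlets** are maximal runs of positions whose moving-average-smoothed
  |contribution| (window 15) strictly exceeds the 0.85 quantile of the
  smoothed track, extended by 5-bp flanks and merged when overlapping. The
  quantile is interpreted *per sequence*, which makes the extractor
  calibration-free across models; the strict inequality means a constant
  track yields no seqlets.

## Global importance analysis (GIA)

A motif's global importance is measured causally: the motif is embedded (by
substitution) at five fixed 1-based positions — 70, 170, 270, 370, 470 in a
500-bp window — in each of up to 1000 background (negative) sequences, and
GIA = mean over backgrounds and positions of `p(embedded) − p(original)`.
Fixed, roughly evenly spaced positions decouple the estimate from any
positional preference of the model; the per-background local importances are
retained so their mean provably equals the global value. A single-nucleotide
GIA map (embedding each of the four bases at each position) and a
top-affinity k-mer extractor (per-column argmax of a PWM) support motif-level
follow-up.

## Motif scanning and co-occurrence

PWMs (JASPAR and minimal-MEME parsers) are regularised with a pseudocount of
0.8 distributed by background frequency, and scored as log₂ odds against the
background. The hit threshold for a requested p-value (default 1e-5, the
conventional cutoff in TFBS scanning) comes from the *exact* null
distribution of the w-mer score, computed by column-by-column convolution of
the per-column score distributions — exact for widths ≤ 8, and on a
granularity grid (score range / 1000 bins) for wider motifs. The DP is
verified against exhaustive 4^w enumeration to 1e-12. When the requested
p-value is below the smallest achievable tail (e.g. an 8-mer against a
uniform background cannot reach 1e-5, since one word already has probability
4⁻⁸ ≈ 1.5e-5), the maximum score is used and a warning is logged — the scan
then reports only exact consensus matches. Both strands are scanned, with
minus-strand hits reported in forward coordinates.

Six aggregation schemes reduce per-motif, per-position scores to one value
per sequence (`M1-SUM`, `M1-MAX`, `SUM-SUM`, `MAX-SUM`, `SUM-MAX`,
`MAX-MAX`; the name is across-motif reduction, then across-position, with
`M1-*` using only the first motif).

Co-occurrence of two motifs over a sample universe is a four-case table
(neither / only A / only B / both), where presence means ≥ 1 hit. The
marginal fractions `frac_a_total` and `frac_b_total` count *all* samples
containing the motif (`only + both`), which is the natural reading of "how
often does motif A occur".

## Metrics

ROC-AUC is delegated to scikit-learn (tested against a brute-force
pair-counting oracle with ties counted half), and thresholded confusion
metrics (TPR/FPR/PPV/NPV/recall, prediction positive iff score ≥ threshold)
return `None` — not 0 — for rates with empty denominators.

## Reproducibility

Every stochastic stage takes an explicit seed. The CLI fans a single
`--seed` out to per-stage seeds via SHA-256, so stages are decoupled (adding
a stage never perturbs another) yet fully determined. Each artifact-producing
subcommand writes a `manifest.json` recording the subcommand, parameters and
package version. Model checkpoints are a zip of the weight arrays plus a JSON
of hyperparameters; a save/load round trip reproduces predictions exactly.

## Limitations

* The NumPy network trains on CPU only; the defaults are sized for hundreds
  of thousands of sequence-epochs, not millions.
* Exact p-value calibration is limited to motif width ≤ 8; wider motifs are
  binned (resolution controlled by `score_bins`).
* The synthetic benchmark plants a single motif instance per positive;
  multi-instance and heterotypic layouts must be composed manually.
* Predictions can differ at the last-ulp level across batch layouts (BLAS
  accumulation order); all contracts are therefore stated to float32
  precision.
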