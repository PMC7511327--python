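# Methods

## The quantile-normalization kernel

All strategies share one kernel (`qnbench.qn`).  For a feature × sample
matrix the *reference distribution* is the vector whose k-th entry is the
mean over samples of each sample's k-th smallest value; normalization
replaces each sample's rank-k value with that entry and restores the
original feature order.  The kernel is exact: each output column's sum
equals the reference sum, so QN preserves the grand sum and equalizes
column sums, and the transform is idempotent.

**Ties.**  The procedure is underdetermined when a sample holds repeated
values.  We give every member of a tied run the mean of the reference values
spanning its rank range ("average ties").  This keeps the transform
deterministic, permutation-equivariant in the feature axis, and
sum-preserving; it is also why a column's output multiset can deviate from
the reference exactly when ties occur.  Values are normalized on the scale
supplied — no internal log transform — with an optional `--log2`
pre-transform on the CLI (default off).

## Strategies

- `all`: the kernel on the full matrix.
- `class_specific` / `discrete`: the kernel per class split, or per
  (class, batch) cell, recombined in the original sample order.  The
  nesting is exact in the degenerate limits: with one class,
  `class_specific` equals `all`; with one batch, `discrete` equals
  `class_specific`; one sample per cell is the identity.
- `ratio`: exactly two classes, equal counts within every batch, strictly
  positive values.  The j-th class-A sample of a batch (in order of
  appearance) is paired with the j-th class-B sample and the pair's column
  is the per-feature ratio B/A.  The pairing is in principle arbitrary, so
  we fix the deterministic order-of-appearance convention for
  reproducibility and expose a seeded random pairing.  The ratio matrix is
  not further quantile-normalized: the transform's point is that the class
  effect becomes a fold change while batch structure survives in the pairs.
- `qsmooth`: per quantile k, with samples' sorted values `x_(k)`, we take
  the total sum of squares SST_k about the overall mean of the k-th order
  statistics and the between-class sum of squares SSB_k about the class
  means; the raw weight is `1 − SSB_k/SST_k` (1 where SST_k = 0), smoothed
  by a centered running median whose window is 5% of the feature count
  (round half-up, minimum 1), clamped to [0, 1].  A sample in class g then
  receives `w_k·Qref_k + (1−w_k)·Qhat_{g,k}` at rank k.  `Qhat` is the
  class-mean fit at each quantile — the one-way layout; richer design
  matrices are not supported.  Weights 1 and 0 recover `all` and
  `class_specific` exactly.  Because the blended target can dip locally
  where w varies, rank assignment deliberately does not require a monotone
  target (`assign_by_rank`); classes of unequal size are compared at common
  ranks since all groups share the feature axis.
- `adjust`: the identity, kept as a first-class strategy so the benchmark
  always carries an unnormalized baseline.

## Simulation model

The base generator emulates a one-class, positive label-free proteomics
intensity matrix: feature i has a log-scale location μ_i ~ N(7, 1.2)
(abundances spanning several orders of magnitude) and samples scatter
around it with log-scale sd 0.25 (~25% CV across samples, typical of
replicate label-free runs).  Samples are split into two equal classes A/B
at random, and within each class half the samples go to each batch.

Class effects: a fraction `cep` ∈ {0, 0.2, 0.5, 0.8} of features (round
half-up) is drawn uniformly; each gets one magnitude m from
{0.2, 0.5, 0.8, 1, 2} (uniform); every class-B value of that feature is
multiplied by 1+m.  One magnitude per feature, not per sample: the effect
level is a property of the feature.  Batch effects mirror this recipe
keyed on the batch factor (`proportional` mode, the default), with the
first batch as untouched reference; a `uniform` mode instead multiplies all
features of each non-reference batch by 1+`batch_level`, for the reading in
which every feature carries some multiplicative batch information.  Both
modes are config fields and reported results must name the mode.  For more
than two batches, each non-reference batch draws its own feature set and
magnitudes in proportional mode.

The technical-replicate generator (`simulate_technical_batches`) emulates a
replicate-run benchmark design: a shared biological matrix is re-measured
once per batch with ~5% log-scale technical noise plus a per-batch,
per-feature multiplicative bias (log-scale sd 0.1) — the natural batch
effect that arises between runs.

What the generators do *not* model: missing values, additive or
non-uniform batch effects, correlated features, count noise, or
platform-specific intensity floors.  Passing benchmarks here show the
strategies' behaviour under clean multiplicative effects with independent
log-normal features; conclusions about real data inherit those assumptions.

## Evaluation

Feature selection is a per-feature two-sample t-test between classes,
batches pooled, at α = 0.05 with no multiplicity correction — the benchmark
measures raw per-feature error rates, and corrected selection would change
the measured magnitudes.  Welch's unequal-variance form is the default
(the simulated effects are heteroscedastic on the raw scale); the pooled
form sits behind `equal_var=True` for sensitivity analysis.  Features with
zero variance in both classes get p = 1.  The ratio strategy is tested by a
one-sample t-test of log2 ratios against 0: the log scale symmetrizes up-
and down-effects and a one-sample test is the natural analogue once the
class effect is a fold change.  This is an interpretation — the ratio
matrix admits other tests — recorded here as the package's choice.
The gPCA delta for the ratio strategy is computed on the ratio matrix with
its per-pair batch labels (the alternative — original samples — is not
used).

Precision, recall and F use the zero conventions (0 when a denominator is
empty) so metrics stay defined at degenerate conditions such as CEP 0.

gPCA delta: features are centered across samples (not variance-scaled) to
give X (samples × features); Y is the unstandardized batch indicator; the
delta is `var(X v_g)/var(X v_u)` with `v_u`, `v_g` the first right singular
vectors of X and YᵀX.  Since each column of X has zero mean, `X v` is
mean-zero and `v_u` maximizes its variance, so the delta lies in (0, 1]
whenever X v_g ≠ 0.  A permutation p-value companion uses add-one
smoothing; note that permutations reproducing the batch partition tie the
observed delta, so 1/(n_perm+1) is a floor, not an attainable exact value.

Ranks: strategies are ranked per condition (rank 1 best; ties share the
mean rank, so half-ranks occur), F-scores descending, deltas ascending.

## The combination scenario

Three one-class batches pass through three phases.  *Adjustment*: each
batch's samples get arbitrary class labels by within-batch order (a
deterministic convention), and one shared draw of differential features and
magnitudes is applied in every batch — the biology is the same everywhere.
*Normalization*: the pairings Batch1+Batch2 and Batch2+Batch3 are each
normalized independently with every strategy.  *Combination*: the two
normalized pairings are merged with deterministic suffixes, so Batch2
appears twice — once per normalization context — and the merged set is
re-evaluated; these duplicated samples are deliberately kept distinct,
because having been normalized under different contexts is precisely the
batch effect the scenario studies, and the pairing of origin serves as the
gPCA batch factor.

The ratio strategy is the structural exception: its pair columns are
computed within batches only, so the transform commutes with combination —
the merged ratio matrix is exactly the concatenation of the per-pairing
outputs, the Batch2 pair block is bitwise identical in both contexts, and
the feature selection on the combined set is identical whether the ratio
transform ran before or after the merge.  The QN strategies do not commute:
their duplicated Batch2 values differ between contexts, which is what
degrades combination-phase selection at low CEP.

## Problem sizes and numerical choices

The shipped benchmarks use 1,000 features × 8 samples with 100 grid
replicates and 50 combination replicates — sizes at which the Monte-Carlo
means are stable to roughly ±0.01 while a full run stays fast on a single
core.  All randomness flows from a single integer seed through
`numpy.random.SeedSequence`-derived child seeds (one per grid cell and
replicate), so every table is byte-reproducible.  Feature-count rounding is
half-up everywhere for cross-platform determinism.  Comparisons against
brute-force oracles in the test suite are exact for the QN kernel (no
ties), 1e-9 for gPCA, and exact rational arithmetic for the confusion
metrics.

## Known limitations

- The t-test operates on raw (or supplied-scale) intensities; no
  variance-stabilizing transform is applied internally.
- The gPCA delta is known to read high when class effects exist without
  batch effects; it is reported as-is, as a summary to be interpreted
  alongside the selection metrics.
- `Qhat` supports only the one-way class layout.
- No missing-value handling: matrices must be complete and non-negative
  (the ratio strategy additionally requires strictly positive values).
- ComBat- and surrogate-variable-style batch correction are out of scope.
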