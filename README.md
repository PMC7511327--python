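# qnbench

Benchmarking quantile-normalization strategies for expression data under
class-effect proportion and batch effects.

## The problem

Quantile normalization (QN) forces every sample of a feature × sample
expression matrix (genes or proteins) onto one shared value distribution:
rank each sample's values, average the values at each rank across samples,
substitute each rank with that average, and restore the original feature
order.  This assumes all samples have similar underlying distributions —
which fails when a large fraction of features is genuinely differential
between sample classes (a high *class-effect proportion*, CEP) or when
technical batches shift distributions.  Applied blindly, QN then erases true
signal and manufactures false positives.

`qnbench` is for analysts and methodologists who want to measure that
failure mode and choose a safer strategy.  It implements six strategies:

- **adjust** — no normalization (the baseline: data after effect insertion);
- **all** — standard QN on the whole matrix;
- **class_specific** — split by class, QN each split independently, recombine;
- **discrete** — split by (class, batch) cell, QN each cell independently;
- **ratio** — replace the matrix by per-feature within-batch B/A sample
  ratios, `r_i = Exp_{S,B,i} / Exp_{S,A,i}`, turning the class effect into a
  fold change while preserving the batch factor;
- **qsmooth** — smooth QN: at rank *k* a sample in class *g* receives
  `w_k·Qref_k + (1−w_k)·Qhat_{g,k}`, where `Qref` is the all-sample reference
  quantile, `Qhat_g` the class-specific quantile, and
  `w_k = 1 − SSB_k/SST_k` (running-median smoothed over a 5% window)
  compares between-class to total variability at that quantile.

Around them sits an evaluation harness: simulation of known multiplicative
class effects (a magnitude *m* drawn from {0.2, 0.5, 0.8, 1, 2} multiplies
affected class-B entries by 1+*m*) and batch effects; per-feature two-sample
*t*-test selection at α = 0.05; precision = TP/(TP+FP),
recall = TP/(TP+FN), F = their harmonic mean against the inserted truth;
the guided-PCA (gPCA) delta `var(X v_guided)/var(X v_unguided)` ∈ (0, 1]
quantifying batch-driven variance; a CEP × batch-level benchmark grid; and a
three-phase *combination* (mega-analysis) scenario that merges datasets
normalized on separate occasions and measures the batch effects that the
merge itself creates.

## Worked example

```python
import qnbench as q

cfg = q.SimulationConfig(n_features=1000, n_samples=8, cep=0.8,
                         batch_level=0.5, seed=7)
ds, truth = q.simulate_dataset(cfg)

for strategy in ("adjust", "all", "class_specific"):
    norm = q.normalize(ds, strategy)
    sel = q.select_features_ttest(norm, alpha=0.05)
    rec = q.precision_recall_f(sel.selected, truth.differential_features)
    delta = q.gpca_delta(norm.values, norm.batches)
    print(f"{strategy:15s} F={rec.f_score:.3f} "
          f"precision={rec.precision:.3f} recall={rec.recall:.3f} "
          f"delta={delta:.3f}")
```

prints

```
adjust          F=0.604 precision=0.978 recall=0.438 delta=0.896
all             F=0.238 precision=0.632 recall=0.146 delta=0.924
class_specific  F=0.605 precision=0.997 recall=0.434 delta=0.429
```

At a high class-effect proportion (80% of the 1,000 features carry a true
effect) with batch effects present, whole-data QN ("all") collapses the
F-score to 0.24 — it normalizes both classes to one average distribution,
destroying most true differences — while class-specific QN keeps the
F-score of the unnormalized data and roughly halves the batch-effect share
of variance (gPCA delta 0.43 vs 0.90).

The same workflow is available from the shell:

```sh
qnbench simulate  --seed 7 --out sim/
qnbench normalize --strategy class_specific \
    --matrix sim/matrix.tsv --sheet sim/samples.tsv --out normalized.tsv
qnbench evaluate  --matrix normalized.tsv --sheet sim/samples.tsv \
    --truth sim/truth.tsv
qnbench benchmark --seed 1 --out grid/      # full CEP x batch grid
qnbench combine   --seed 1 --out combo/     # three-phase combination scenario
```

Matrices are delimited text (features in rows, first column = feature id,
header = sample ids); sample sheets have columns `sample_id`, `class`,
`batch`.  Every Monte-Carlo command requires a seed and writes its resolved
configuration and a log next to its outputs.

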