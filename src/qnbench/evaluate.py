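"""Feature selection, confusion metrics, and gPCA batch-effect quantification.

Selection uses a per-feature two-sample t test between classes at a fixed
significance level (no multiplicity correction: the benchmark measures raw
per-feature error rates).  Batch-effect strength is summarized by the guided
PCA (gPCA) delta: the variance captured along the first batch-guided
principal direction divided by the variance along the first unguided
principal direction — close to 1 when batch dominates the total variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, Dataset
from .strategies import RatioDataset

__all__ = [
    "SelectionResult",
    "MetricsRecord",
    "select_features_ttest",
    "select_features_ratio",
    "precision_recall_f",
    "gpca_delta",
    "gpca_permutation_p",
    "rank_methods",
]


@dataclass
class SelectionResult:
    """Features called differential at level ``alpha`` with their p-values."""

    selected: set[str]
    p_values: pd.Series
    alpha: float


@dataclass
class MetricsRecord:
    """Confusion counts and derived rates for one evaluated condition."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    gpca_delta: float | None = None


def select_features_ttest(
    ds: Dataset, alpha: float = 0.05, equal_var: bool = False
) -> SelectionResult:
    """Per-feature two-sample t test between the two classes, pooling batches.

    Welch's unequal-variance form by default (``equal_var=True`` for the
    pooled-variance Student form).  Degenerate features with zero variance in
    both classes get p = 1.  Selected features are those with p < alpha.
    """
    levels = sorted(set(ds.classes))
    if len(levels) != 2:
        raise DataError(f"t-test selection needs exactly 2 classes, got {levels}")
    a_cols = [s for s, c in ds.classes.items() if c == levels[0]]
    b_cols = [s for s, c in ds.classes.items() if c == levels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DataError("each class needs >= 2 samples")
    a = ds.values[a_cols].to_numpy()
    b = ds.values[b_cols].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant features trigger scipy's precision-loss warning; their
        # p-values come out nan and are set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # zero within-class variance in both classes
    p_values = pd.Series(p, index=ds.feature_ids)
    return SelectionResult(
        selected=set(p_values.index[p_values < alpha]), p_values=p_values, alpha=alpha
    )


def select_features_ratio(rds: RatioDataset, alpha: float = 0.05) -> SelectionResult:
    """One-sample t test of log2 ratios against 0, per feature.

    A feature with a consistent class fold-change has log-ratios centered off
    0 across the pairs; at least two pairs are needed for a variance estimate.
    """
    if rds.n_pairs < 2:
        raise DataError("insufficient pairs: ratio test needs >= 2 ratio columns")
    logr = np.log2(rds.values.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(logr, 0.0, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    p_values = pd.Series(p, index=rds.feature_ids)
    return SelectionResult(
        selected=set(p_values.index[p_values < alpha]), p_values=p_values, alpha=alpha
    )


def precision_recall_f(
    selected: set, truth: set, n_features: int | None = None
) -> MetricsRecord:
    """Confusion counts of a selection against the ground-truth set.

    Precision = TP/(TP+FP), Recall = TP/(TP+FN), F = their harmonic mean;
    empty denominators yield 0 so the metrics stay defined at degenerate
    conditions (e.g. nothing selected, or no true effects).
    """
    selected = set(selected)
    truth = set(truth)
    if n_features is not None:
        if len(selected | truth) > n_features:
            raise ValueError("selection/truth exceed the feature universe")
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricsRecord(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f_score=f)


def _gpca_directions(values, batch_labels):
    """Centered sample x feature matrix, batch indicator, and the two
    first right singular vectors (unguided and guided)."""
    arr = np.asarray(values, dtype=float)
    labels = np.asarray(list(batch_labels))
    n_features, n_samples = arr.shape
    if labels.shape[0] != n_samples:
        raise ValueError("one batch label per sample required")
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) < 2:
        raise DataError("gPCA needs >= 2 batches")
    if n_samples < 2 or n_features < 2:
        raise DataError("gPCA needs >= 2 samples and >= 2 features")
    x = arr.T - arr.mean(axis=1)  # samples x features, features centered
    if not np.any(x):
        raise DataError("constant matrix has no variance to attribute")
    y = np.stack([(labels == lv).astype(float) for lv in levels], axis=1)
    v_u = np.linalg.svd(x, full_matrices=False)[2][0]
    v_g = np.linalg.svd(y.T @ x, full_matrices=False)[2][0]
    return x, y, v_u, v_g


def gpca_delta(values, batch_labels) -> float:
    """Guided-PCA delta: var(X v_guided) / var(X v_unguided), in (0, 1].

    ``values`` is a feature x sample matrix (array or DataFrame); each feature
    is centered across samples, the unguided direction is the first right
    singular vector of the centered matrix X, and the guided direction the
    first right singular vector of Y'X with Y the batch indicator matrix.
    """
    x, _, v_u, v_g = _gpca_directions(values, batch_labels)
    return float(np.var(x @ v_g) / np.var(x @ v_u))


def gpca_permutation_p(
    values, batch_labels, n_perm: int, seed: int | np.random.Generator = 0
) -> float:
    """Permutation p-value for the gPCA delta (add-one smoothing)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(batch_labels))
    observed = gpca_delta(values, labels)
    hits = 0
    for _ in range(n_perm):
        if gpca_delta(values, rng.permutation(labels)) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def rank_methods(scores: dict, higher_is_better: bool) -> dict:
    """Rank strategies by score (rank 1 = best; ties share the mean rank)."""
    if not scores:
        raise ValueError("empty score map")
    names = list(scores)
    vals = np.asarray([scores[n] for n in names], dtype=float)
    ranks = stats.rankdata(-vals if higher_is_better else vals, method="average")
    return {n: float(r) for n, r in zip(names, ranks)}
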