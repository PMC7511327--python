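"""The five quantile-normalization strategies, plus the "adjust" baseline.

* ``adjust`` — no-op baseline: data after effect insertion, before any
  normalization.
* ``all`` — standard QN on the whole matrix, ignoring class and batch.
* ``class_specific`` — split by class, QN each split independently, recombine.
* ``discrete`` — split by (class, batch) cell, QN each cell independently.
* ``ratio`` — pair samples of the two classes within each batch and replace
  the matrix by per-feature B/A expression ratios, turning the class effect
  into a fold change while preserving the batch factor.
* ``qsmooth`` — weighted QN that interpolates, per quantile, between the
  all-sample reference (Qref) and the group-specific quantiles (Qhat) with a
  weight w derived from between- vs total-group variability at that quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataError, Dataset
from .qn import assign_by_rank, quantile_normalize, reference_distribution

__all__ = [
    "STRATEGY_NAMES",
    "RatioDataset",
    "QsmoothFit",
    "normalize",
    "normalize_all",
    "normalize_class_specific",
    "normalize_discrete",
    "ratio_transform",
    "qsmooth_weights",
    "qsmooth_normalize",
]

STRATEGY_NAMES = ("adjust", "all", "class_specific", "discrete", "ratio", "qsmooth")


@dataclass
class RatioDataset:
    """Feature x pair matrix of B/A expression ratios.

    ``values`` columns are one per within-batch (A, B) sample pair, named
    ``"B_sample/A_sample"``; ``batches`` carries the batch label of each pair.
    """

    values: pd.DataFrame
    batches: pd.Series

    def __post_init__(self) -> None:
        if list(self.batches.index) != list(self.values.columns):
            raise DataError("annotation mismatch: pair batch labels")
        if (self.values.to_numpy() <= 0).any():
            raise DataError("ratios must be strictly positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


@dataclass
class QsmoothFit:
    """Fitted qsmooth components: reference quantiles, per-group quantiles,
    and the per-quantile shrinkage weights."""

    qref: np.ndarray              # ascending, length n_features
    qhat: pd.DataFrame            # n_features x n_groups, columns = class labels
    weights: np.ndarray           # in [0, 1], length n_features


def normalize(ds: Dataset, strategy: str, **kwargs):
    """Dispatch to one of the six strategies.

    Returns a :class:`Dataset` for every strategy except ``ratio``, which
    returns a :class:`RatioDataset`.
    """
    if strategy == "adjust":
        return ds.copy()
    if strategy == "all":
        return normalize_all(ds)
    if strategy == "class_specific":
        return normalize_class_specific(ds)
    if strategy == "discrete":
        return normalize_discrete(ds)
    if strategy == "ratio":
        return ratio_transform(ds, **kwargs)
    if strategy == "qsmooth":
        return qsmooth_normalize(ds, **kwargs)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGY_NAMES}")


def normalize_all(ds: Dataset) -> Dataset:
    """QN on the complete matrix, irrespective of class and batch factors."""
    return ds.with_values(quantile_normalize(ds.values))


def _normalize_groups(ds: Dataset, keys: pd.Series) -> Dataset:
    out = ds.values.copy()
    for key in dict.fromkeys(keys):
        ids = [s for s, k in keys.items() if k == key]
        out[ids] = quantile_normalize(ds.values[ids])
    return ds.with_values(out)


def normalize_class_specific(ds: Dataset) -> Dataset:
    """QN applied independently within each class; splits recombined in the
    original sample order."""
    return _normalize_groups(ds, ds.classes)


def normalize_discrete(ds: Dataset) -> Dataset:
    """QN applied independently within each (class, batch) cell."""
    keys = pd.Series(list(zip(ds.classes, ds.batches)), index=ds.classes.index)
    return _normalize_groups(ds, keys)


def ratio_transform(
    ds: Dataset, pairing: str = "ordered", rng: np.random.Generator | None = None
) -> RatioDataset:
    """Per-feature B/A ratios from within-batch sample pairs.

    Requires exactly two classes with equal counts inside every batch and
    strictly positive intensities.  With ``pairing="ordered"`` (default) the
    j-th A sample of a batch is paired with the j-th B sample, in order of
    appearance; ``pairing="random"`` shuffles the pairing using ``rng``.
    """
    levels = sorted(set(ds.classes))
    if len(levels) != 2:
        raise DataError(f"ratio strategy needs exactly 2 classes, got {levels}")
    if (ds.values.to_numpy() <= 0).any():
        raise DataError("ratio strategy requires strictly positive intensities")
    cls_a, cls_b = levels
    cols: list[pd.Series] = []
    names: list[str] = []
    pair_batches: list = []
    for batch in ds.batch_levels:
        in_batch = [s for s, b in ds.batches.items() if b == batch]
        a_ids = [s for s in in_batch if ds.classes[s] == cls_a]
        b_ids = [s for s in in_batch if ds.classes[s] == cls_b]
        if len(a_ids) != len(b_ids):
            raise DataError(
                f"unbalanced pairing in batch {batch!r}: "
                f"{len(a_ids)} x {cls_a} vs {len(b_ids)} x {cls_b}"
            )
        if pairing == "random":
            if rng is None:
                raise ValueError("random pairing requires rng")
            a_ids = [a_ids[i] for i in rng.permutation(len(a_ids))]
            b_ids = [b_ids[i] for i in rng.permutation(len(b_ids))]
        elif pairing != "ordered":
            raise ValueError(f"unknown pairing {pairing!r}")
        for a, b in zip(a_ids, b_ids):
            cols.append(ds.values[b] / ds.values[a])
            names.append(f"{b}/{a}")
            pair_batches.append(batch)
    values = pd.concat(cols, axis=1)
    values.columns = names
    return RatioDataset(values, pd.Series(pair_batches, index=names, dtype=object))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def qsmooth_weights(
    sorted_matrix: np.ndarray,
    class_labels,
    window: int | None = None,
) -> np.ndarray:
    """Per-quantile shrinkage weights from between- vs total-group variability.

    ``sorted_matrix`` holds each sample's values sorted ascending (one column
    per sample).  At quantile k the raw weight is ``1 - SSB_k / SST_k`` where
    SST_k is the total sum of squares of the k-th order statistics about their
    overall mean and SSB_k the between-group sum of squares about the group
    means (weight 1 when SST_k = 0).  The raw weights are then smoothed with a
    running median whose window defaults to 5% of the feature count, and
    clamped to [0, 1].
    """
    sorted_matrix = np.asarray(sorted_matrix, dtype=float)
    labels = np.asarray(list(class_labels))
    n_features, n_samples = sorted_matrix.shape
    if labels.shape[0] != n_samples:
        raise ValueError("one class label per sample required")
    groups = list(dict.fromkeys(labels.tolist()))
    if len(groups) < 2:
        raise DataError("qsmooth needs at least 2 classes")
    qref = sorted_matrix.mean(axis=1)
    sst = ((sorted_matrix - qref[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(n_features)
    for g in groups:
        members = labels == g
        if members.sum() < 2:
            raise DataError(f"class {g!r} has fewer than 2 samples")
        qhat_g = sorted_matrix[:, members].mean(axis=1)
        ssb += members.sum() * (qhat_g - qref) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(sst > 0, 1.0 - ssb / sst, 1.0)
    if window is None:
        window = max(1, _round_half_up(0.05 * n_features))
    smooth = (
        pd.Series(raw).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    return np.clip(smooth, 0.0, 1.0)


def _qsmooth_fit(ds: Dataset, weights: np.ndarray | None) -> QsmoothFit:
    arr = ds.values.to_numpy()
    sorted_matrix = np.sort(arr, axis=0)
    labels = ds.classes.to_numpy()
    groups = list(dict.fromkeys(labels.tolist()))
    if weights is None:
        weights = qsmooth_weights(sorted_matrix, labels)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (ds.n_features,):
            raise ValueError("one weight per quantile required")
        if np.any((weights < 0) | (weights > 1)):
            raise ValueError("weights must lie in [0, 1]")
    qref = reference_distribution(arr)
    qhat = pd.DataFrame(
        {g: sorted_matrix[:, labels == g].mean(axis=1) for g in groups},
        index=ds.values.index,
    )
    return QsmoothFit(qref=qref, qhat=qhat, weights=weights)


def qsmooth_normalize(
    ds: Dataset,
    weights: np.ndarray | None = None,
    return_fit: bool = False,
):
    """Smooth quantile normalization.

    A sample in group g receives, at rank k, the value
    ``w_k * Qref_k + (1 - w_k) * Qhat_{g,k}`` restored to its original gene
    order.  With all weights 1 this is whole-data QN; with all weights 0 it is
    class-specific QN.  Pass ``weights`` to override the fitted weights;
    ``return_fit=True`` additionally returns the :class:`QsmoothFit`.
    """
    if len(ds.class_levels) < 2:
        raise DataError("qsmooth needs at least 2 classes")
    fit = _qsmooth_fit(ds, weights)
    out = ds.values.copy()
    for g in fit.qhat.columns:
        target = fit.weights * fit.qref + (1.0 - fit.weights) * fit.qhat[g].to_numpy()
        ids = [s for s, c in ds.classes.items() if c == g]
        out[ids] = assign_by_rank(ds.values[ids], target)
    result = ds.with_values(out)
    if return_fit:
        return result, fit
    return result
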