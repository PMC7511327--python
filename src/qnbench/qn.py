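"""The core quantile-normalization transform.

Quantile normalization forces every sample (column) of a feature x sample
matrix to share one value distribution: rank each sample's values, average
the values occupying each rank across samples (the *reference distribution*),
substitute each rank's value with that average, and restore the original
feature order per sample.

Ties within a sample receive the mean of the reference values spanning their
rank range (the "average ties" convention), which keeps the transform
deterministic and invariant under feature permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "reference_distribution",
    "assign_by_rank",
    "normalize_to_reference",
    "quantile_normalize",
]


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("empty matrix")
    return arr


def reference_distribution(values) -> np.ndarray:
    """Mean of the k-th smallest value across samples, for every rank k.

    Accepts a features x samples array or DataFrame; returns an ascending
    vector of length ``n_features``.
    """
    arr = _as_2d(values)
    return np.sort(arr, axis=0).mean(axis=1)


def _map_column(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    sorted_vals = col[order]
    # group consecutive equal values; tied entries share the mean of the
    # reference values covering their rank range
    new_group = np.r_[True, sorted_vals[1:] != sorted_vals[:-1]]
    group_ids = np.cumsum(new_group) - 1
    sums = np.bincount(group_ids, weights=ref)
    counts = np.bincount(group_ids)
    assigned = (sums / counts)[group_ids]
    out = np.empty_like(assigned)
    out[order] = assigned
    return out


def assign_by_rank(values, target) -> pd.DataFrame | np.ndarray:
    """Replace each sample's rank-k value with ``target[k]``, keeping gene order.

    ``target`` is indexed by rank but need not be monotone (the qsmooth
    per-group targets are quantile-wise blends and may dip locally).  The
    return type matches the input (DataFrame in, DataFrame out).
    """
    arr = _as_2d(values)
    target = np.asarray(target, dtype=float)
    if target.shape != (arr.shape[0],):
        raise ValueError(
            f"reference length {target.shape} does not match feature count {arr.shape[0]}"
        )
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = _map_column(arr[:, j], target)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def normalize_to_reference(values, ref) -> pd.DataFrame | np.ndarray:
    """:func:`assign_by_rank` against a proper (non-decreasing) reference."""
    ref = np.asarray(ref, dtype=float)
    if np.any(np.diff(ref) < 0):
        raise ValueError("reference distribution must be non-decreasing")
    return assign_by_rank(values, ref)


def quantile_normalize(values) -> pd.DataFrame | np.ndarray:
    """Standard quantile normalization of a features x samples matrix."""
    return normalize_to_reference(values, reference_distribution(values))
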