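"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by the most literal route available
(explicit per-sample loops, eigendecomposition instead of SVD, exact
fractions) and share no code with the package.
"""

from fractions import Fraction

import numpy as np


def qn_oracle(arr: np.ndarray) -> np.ndarray:
    """Literal sort/average/unsort quantile normalization (no tie handling,
    so only valid on matrices with distinct values within each column)."""
    arr = np.asarray(arr, dtype=float)
    n_features, n_samples = arr.shape
    ref = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(n_samples):
        order = np.argsort(arr[:, j], kind="stable")
        for rank, idx in enumerate(order):
            out[idx, j] = ref[rank]
    return out


def gpca_oracle(values, batch_labels) -> float:
    """gPCA delta via covariance eigendecomposition (independent of SVD)."""
    arr = np.asarray(values, dtype=float)
    labels = np.asarray(list(batch_labels))
    x = arr.T - arr.mean(axis=1)
    levels = sorted(set(labels.tolist()))
    y = np.stack([(labels == lv).astype(float) for lv in levels], axis=1)
    _, vecs = np.linalg.eigh(x.T @ x)
    v_u = vecs[:, -1]
    m = y.T @ x
    _, vecs_g = np.linalg.eigh(m.T @ m)
    v_g = vecs_g[:, -1]
    return float(np.var(x @ v_g) / np.var(x @ v_u))


def prf_oracle(tp: int, fp: int, fn: int) -> tuple[Fraction, Fraction, Fraction]:
    """Exact-rational precision/recall/F with the zero-denominator convention."""
    precision = Fraction(tp, tp + fp) if tp + fp > 0 else Fraction(0)
    recall = Fraction(tp, tp + fn) if tp + fn > 0 else Fraction(0)
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = Fraction(0)
    return precision, recall, f


def qsmooth_weights_oracle(sorted_matrix: np.ndarray, labels) -> np.ndarray:
    """Direct re-computation of the qsmooth weights: per-quantile
    1 - SSB/SST followed by a centered running median over a 5% window."""
    sorted_matrix = np.asarray(sorted_matrix, dtype=float)
    labels = list(labels)
    n_features, n_samples = sorted_matrix.shape
    raw = np.empty(n_features)
    for k in range(n_features):
        row = sorted_matrix[k]
        grand = row.mean()
        sst = float(((row - grand) ** 2).sum())
        ssb = 0.0
        for g in set(labels):
            members = [i for i, lab in enumerate(labels) if lab == g]
            ssb += len(members) * (row[members].mean() - grand) ** 2
        raw[k] = 1.0 - ssb / sst if sst > 0 else 1.0
    window = int(np.floor(0.05 * n_features + 0.5))
    window = max(1, window)
    smoothed = np.empty(n_features)
    # centered window spanning [k - w//2, k + (w-1)//2], truncated at edges
    half_left = window // 2
    half_right = (window - 1) // 2
    for k in range(n_features):
        lo = max(0, k - half_left)
        hi = min(n_features, k + half_right + 1)
        smoothed[k] = np.median(raw[lo:hi])
    return np.clip(smoothed, 0.0, 1.0)
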