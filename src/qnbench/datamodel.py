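"""Expression-matrix container with class/batch sample annotation, plus
delimited-text readers and writers.

A :class:`Dataset` holds a positive-valued feature-by-sample intensity matrix
(genes or proteins in rows, samples in columns) together with one class label
and one batch label per sample.  Matrices are stored as :class:`pandas.DataFrame`
with feature identifiers on the index and sample identifiers on the columns;
labels are :class:`pandas.Series` indexed by sample identifier in column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "split_dataset",
    "merge_datasets",
]


class DataError(ValueError):
    """Raised when an expression matrix or sample sheet violates an invariant."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _check_matrix(values: pd.DataFrame) -> None:
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise DataError("empty matrix")
    if values.index.duplicated().any():
        raise DataError("duplicate feature ids")
    if values.columns.duplicated().any():
        raise DataError("duplicate sample ids")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise DataError("non-numeric intensity")
    if not np.isfinite(arr).all():
        raise DataError("non-finite intensity")
    if (arr < 0).any():
        raise DataError("negative intensity")


@dataclass
class Dataset:
    """A feature x sample intensity matrix with per-sample class/batch labels.

    Parameters
    ----------
    values
        Feature x sample matrix; index = feature ids, columns = sample ids.
    classes
        Class label per sample, indexed by sample id in column order.
    batches
        Batch label per sample, indexed by sample id in column order.
    """

    values: pd.DataFrame
    classes: pd.Series
    batches: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.classes = pd.Series(self.classes, dtype=object)
        self.batches = pd.Series(self.batches, dtype=object)
        _check_matrix(self.values)
        cols = list(self.values.columns)
        for name, lab in (("class", self.classes), ("batch", self.batches)):
            if list(lab.index) != cols:
                raise DataError(
                    f"annotation mismatch: {name} labels do not cover the "
                    "matrix samples in order"
                )
            if lab.isna().any():
                raise DataError(f"annotation mismatch: missing {name} label")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def class_levels(self) -> list:
        return list(dict.fromkeys(self.classes))

    @property
    def batch_levels(self) -> list:
        return list(dict.fromkeys(self.batches))

    def annotation(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame with columns sample_id, class, batch."""
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "class": self.classes.to_numpy(),
                "batch": self.batches.to_numpy(),
            }
        )

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), self.classes.copy(), self.batches.copy())

    def with_values(self, values: pd.DataFrame) -> "Dataset":
        """Same annotation, new matrix (must keep feature/sample axes)."""
        if list(values.columns) != self.sample_ids:
            raise DataError("annotation mismatch: sample axis changed")
        return Dataset(values, self.classes.copy(), self.batches.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "Dataset":
        ids = list(sample_ids)
        return Dataset(
            self.values[ids].copy(), self.classes[ids].copy(), self.batches[ids].copy()
        )

    def equals(self, other: "Dataset", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and list(self.classes) == list(other.classes)
            and list(self.batches) == list(other.batches)
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
        )


def read_dataset(
    matrix_path: str | Path,
    sheet_path: str | Path,
    transpose: bool = False,
) -> Dataset:
    """Read a delimited expression matrix and its sample sheet.

    The matrix file has features in rows (first column = feature id, header
    row = sample ids); pass ``transpose=True`` for samples-in-rows files.
    The sheet requires columns ``sample_id``, ``class`` and ``batch``.
    Delimiter is inferred from the extension (``.csv`` comma, else tab).
    """
    values = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    if transpose:
        values = values.T
    if values.size == 0:
        raise DataError("empty matrix")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric intensity: {exc}") from exc

    sheet = pd.read_csv(sheet_path, sep=_sep_for(sheet_path))
    sheet.columns = [str(c).strip() for c in sheet.columns]
    required = {"sample_id", "class", "batch"}
    if not required.issubset(sheet.columns):
        raise DataError(
            f"sample sheet must have columns {sorted(required)}, got {list(sheet.columns)}"
        )
    sheet = sheet.set_index("sample_id")
    if sheet.index.duplicated().any():
        raise DataError("annotation mismatch: duplicate sample_id in sheet")
    missing = [s for s in values.columns if s not in sheet.index]
    extra = [s for s in sheet.index if s not in values.columns]
    if missing or extra:
        raise DataError(
            f"annotation mismatch: missing={missing} extra={extra}"
        )
    sheet = sheet.loc[list(values.columns)]
    return Dataset(values, sheet["class"], sheet["batch"])


def write_dataset(
    ds: Dataset, matrix_path: str | Path, sheet_path: str | Path
) -> None:
    """Write a Dataset back to delimited text (full float precision)."""
    ds.values.to_csv(matrix_path, sep=_sep_for(matrix_path), index_label="feature_id")
    ds.annotation().to_csv(sheet_path, sep=_sep_for(sheet_path), index=False)


def split_dataset(ds: Dataset, by: str) -> list[tuple[object, Dataset]]:
    """Partition samples by ``class``, ``batch`` or ``class_and_batch``.

    Keys appear in order of first appearance along the sample axis; the
    splits partition the samples, so concatenating them and restoring the
    original column order reproduces the input.
    """
    if by == "class":
        keys = ds.classes
    elif by == "batch":
        keys = ds.batches
    elif by == "class_and_batch":
        keys = pd.Series(
            list(zip(ds.classes, ds.batches)), index=ds.classes.index
        )
    else:
        raise ValueError(f"unknown grouping {by!r}")
    out: list[tuple[object, Dataset]] = []
    for key in dict.fromkeys(keys):
        ids = [s for s, k in keys.items() if k == key]
        if not ids:  # cannot occur by construction; guard anyway
            raise DataError(f"grouping level {key!r} has zero samples")
        out.append((key, ds.subset_samples(ids)))
    return out


def merge_datasets(
    parts: Iterable[Dataset],
    sample_order: Sequence[str] | None = None,
    suffixes: Sequence[str] | None = None,
) -> Dataset:
    """Column-concatenate Datasets sharing one feature axis.

    Sample ids must be disjoint across parts unless ``suffixes`` provides one
    disambiguating suffix per part (applied to every sample of that part, so
    a sample normalized twice in different contexts stays visible twice).
    ``sample_order`` reorders the merged columns.
    """
    parts = list(parts)
    if not parts:
        raise DataError("empty matrix")
    ref_features = parts[0].feature_ids
    for p in parts[1:]:
        if p.feature_ids != ref_features:
            raise DataError("feature mismatch between merged parts")
    if suffixes is not None:
        if len(suffixes) != len(parts):
            raise DataError("one suffix per part required")
        renamed = []
        for p, suf in zip(parts, suffixes):
            mapping = {s: f"{s}{suf}" for s in p.sample_ids}
            renamed.append(
                Dataset(
                    p.values.rename(columns=mapping),
                    p.classes.rename(index=mapping),
                    p.batches.rename(index=mapping),
                )
            )
        parts = renamed
    all_ids = [s for p in parts for s in p.sample_ids]
    if len(set(all_ids)) != len(all_ids):
        raise DataError("duplicate sample id without suffix policy")
    values = pd.concat([p.values for p in parts], axis=1)
    classes = pd.concat([p.classes for p in parts])
    batches = pd.concat([p.batches for p in parts])
    ds = Dataset(values, classes, batches)
    if sample_order is not None:
        if sorted(sample_order) != sorted(all_ids):
            raise DataError("sample_order does not match merged samples")
        ds = ds.subset_samples(list(sample_order))
    return ds
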