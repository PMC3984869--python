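"""Dataset container, z-normalization, and UCR-style delimited I/O.

A time series here is a 1-D float array of length ``n >= 2`` with no missing
values; a dataset is an ``(N, n)`` matrix of such series, all of equal length,
optionally carrying one integer ground-truth class label per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "z_normalize",
    "validate_dataset",
    "load_ucr",
    "save_ucr",
]


def z_normalize(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize a series (or each row of a matrix) to mean 0, sd 1.

    Uses the population standard deviation (``ddof=0``) so the result is
    invariant to affine rescaling ``a*x + b`` with ``a > 0``; pass ``ddof=1``
    for the sample convention. A constant series (sd = 0) maps to the
    all-zeros series with a warning rather than raising, so degenerate
    fixtures do not abort a pipeline.
    """
    x = np.asarray(values, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=ddof, keepdims=True)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            "constant series encountered during z-normalization; mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    sd = np.where(flat, 1.0, sd)
    out = (x - mu) / sd
    if np.any(flat):
        out = np.where(np.broadcast_to(flat, out.shape), 0.0, out)
    return out


@dataclass
class TimeSeriesDataset:
    """Equal-length time-series collection with optional class labels.

    Attributes
    ----------
    values : (N, n) float array, one series per row.
    labels : optional (N,) integer array of ground-truth class ids.
    ids : per-series identifiers (defaults to row indices).
    """

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    ids: Sequence = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N, n) array")
        if self.values.shape[1] < 2:
            raise ValueError("series must have length >= 2")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(
                f"non-finite value at (row, col) {[tuple(b) for b in bad[:5]]}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels must provide one class id per series")
        if self.ids is None:
            self.ids = list(range(self.values.shape[0]))
        elif len(self.ids) != self.values.shape[0]:
            raise ValueError("ids must provide one identifier per series")

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            return 0
        return int(np.unique(self.labels).size)

    def z_normalized(self, ddof: int = 0) -> "TimeSeriesDataset":
        """Return a copy with every series standardized to mean 0, sd 1."""
        return TimeSeriesDataset(
            z_normalize(self.values, ddof=ddof), labels=self.labels, ids=self.ids
        )


def validate_dataset(
    rows: Sequence[Sequence[float]], labels: Optional[Sequence[int]] = None
) -> TimeSeriesDataset:
    """Build a dataset from raw rows, diagnosing ragged or non-finite input.

    Raises
    ------
    ValueError
        With the offending row indices for unequal lengths, or the (row,
        column) position for non-numeric / non-finite entries.
    """
    lengths = [len(r) for r in rows]
    if not rows:
        raise ValueError("empty dataset")
    if len(set(lengths)) > 1:
        common = max(set(lengths), key=lengths.count)
        bad = [i for i, ln in enumerate(lengths) if ln != common]
        raise ValueError(f"unequal length rows at indices {bad} (expected {common})")
    parsed = np.empty((len(rows), lengths[0]), dtype=np.float64)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            try:
                parsed[i, j] = float(tok)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"non-numeric value {tok!r} at row {i}, column {j}"
                ) from exc
    return TimeSeriesDataset(parsed, labels=None if labels is None else labels)


def load_ucr(path, labeled: bool = True, delimiter: Optional[str] = None) -> TimeSeriesDataset:
    """Read a UCR-style delimited file: one series per row, optional integer
    class label in column 1. ``delimiter=None`` sniffs comma/tab/whitespace."""
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "," if "," in first else ("\t" if "\t" in first else r"\s+")
    df = pd.read_csv(path, sep=delimiter, header=None, engine="python")
    arr = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
    if labeled:
        labels = arr[:, 0]
        if not np.allclose(labels, np.round(labels)):
            raise ValueError("first column must hold integer class labels")
        return TimeSeriesDataset(arr[:, 1:], labels=labels.astype(int))
    return TimeSeriesDataset(arr)


def save_ucr(dataset: TimeSeriesDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset as a UCR-style delimited file (label column first
    when labels are present)."""
    if dataset.labels is not None:
        data = np.column_stack([dataset.labels.astype(float), dataset.values])
    else:
        data = dataset.values
    np.savetxt(path, data, delimiter=delimiter, fmt="%.10g")
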