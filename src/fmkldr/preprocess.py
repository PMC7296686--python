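"""Cleaning and rescaling of sample-by-feature matrices.

Raw multi-omic or imaging-derived views arrive as real matrices with one
row per sample and one column per feature, possibly with missing cells.
Before kernel construction each view is (a) stripped of any feature that
is missing in at least one sample and (b) min-max rescaled per feature
into a common range, by default [-1, 1], so that views with very
different magnitudes contribute comparably to Euclidean distances.

Scaling statistics are learned on the training split only and re-applied
to held-out samples (with clipping into the target range), so that the
holdout protocol never sees test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "drop_incomplete_features",
    "MinMaxRescaler",
    "minmax_rescale",
    "read_feature_matrix",
    "write_feature_matrix",
]


class EmptyMatrixError(ValueError):
    """Raised when an operation would leave a matrix with no features."""


@dataclass
class FeatureMatrix:
    """A samples x features real matrix with identifiers and missing mask.

    Parameters
    ----------
    values
        Real matrix of shape (n_samples, n_features). Entries under the
        missing mask are ignored (conventionally NaN).
    sample_ids, feature_ids
        Unique string identifiers matching the matrix dimensions.
    missing_mask
        Boolean matrix, True where the value is missing. Defaults to the
        NaN pattern of ``values``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids are not unique")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def subset_samples(self, index: Sequence[int]) -> "FeatureMatrix":
        """Return a view restricted to the given sample positions."""
        idx = np.asarray(index, dtype=int)
        return FeatureMatrix(
            self.values[idx].copy(),
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.missing_mask[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.feature_ids)


def drop_incomplete_features(X: FeatureMatrix) -> FeatureMatrix:
    """Remove every feature column that is missing in any sample.

    Column order and the sample set are preserved. Missing data is handled
    only by removal, never by imputation.

    Raises
    ------
    EmptyMatrixError
        If every feature has at least one missing value.
    """
    keep = ~X.missing_mask.any(axis=0)
    if not keep.any():
        raise EmptyMatrixError("all features have missing values; empty matrix")
    return FeatureMatrix(
        X.values[:, keep].copy(),
        list(X.sample_ids),
        [f for f, k in zip(X.feature_ids, keep) if k],
        X.missing_mask[:, keep].copy(),
    )


@dataclass
class MinMaxRescaler:
    """Per-feature min-max map onto [lo, hi], fitted on training samples.

    A constant feature column maps to the range midpoint, which keeps the
    feature dimensionality stable across views instead of dropping or
    erroring on degenerate columns. Transformed values of unseen samples
    are clipped into [lo, hi].
    """

    lo: float = -1.0
    hi: float = 1.0
    mins_: np.ndarray | None = None
    maxs_: np.ndarray | None = None

    def fit(self, X: FeatureMatrix) -> "MinMaxRescaler":
        if not X.is_complete():
            raise ValueError("rescaler requires a complete matrix; drop or clean first")
        if self.hi <= self.lo:
            raise ValueError("hi must exceed lo")
        self.mins_ = X.values.min(axis=0)
        self.maxs_ = X.values.max(axis=0)
        return self

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        if self.mins_ is None or self.maxs_ is None:
            raise ValueError("rescaler not fitted")
        if X.n_features != self.mins_.shape[0]:
            raise ValueError("feature count differs from the fitted matrix")
        span = self.maxs_ - self.mins_
        mid = 0.5 * (self.lo + self.hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = self.lo + (self.hi - self.lo) * (X.values - self.mins_) / span
        scaled = np.where(span == 0, mid, scaled)
        scaled = np.clip(scaled, self.lo, self.hi)
        return FeatureMatrix(scaled, list(X.sample_ids), list(X.feature_ids))

    def fit_transform(self, X: FeatureMatrix) -> FeatureMatrix:
        return self.fit(X).transform(X)


def minmax_rescale(X: FeatureMatrix, lo: float = -1.0, hi: float = 1.0) -> FeatureMatrix:
    """Rescale each feature column of a complete matrix into [lo, hi]."""
    return MinMaxRescaler(lo=lo, hi=hi).fit_transform(X)


def read_feature_matrix(path: str | Path, sep: str | None = None) -> FeatureMatrix:
    """Read a delimited matrix: first row feature ids, first column sample ids.

    Empty cells and "NA" denote missing values. The delimiter is inferred
    from the extension (``.csv`` -> comma, otherwise tab) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_feature_matrix(X: FeatureMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    X.to_frame().to_csv(path, sep=sep, na_rep="NA")
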