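"""Canonical data model for incomplete multivariate time series.

A series is a matrix of ``n`` timestamps by ``d`` attributes.  The binary mask
``M`` is the single source of truth for missingness (``M[t, j] = 1`` iff the
entry is observed); in the ``values`` array missing entries are stored as NaN
but the mask, not the NaN, is canonical.  The time-lag matrix ``delta`` records
per attribute the elapsed time since the last observed value, accumulating
across consecutive gaps:

    delta[0, j] = 0
    delta[t, j] = s_t - s_{t-1}            if M[t-1, j] = 1
    delta[t, j] = s_t - s_{t-1} + delta[t-1, j]   otherwise

where ``s_t`` are the timestamps.  This staleness signal drives the time-decay
mechanism of the imputation network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "Scaler",
    "compute_mask",
    "compute_time_lag",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "segment",
    "inject_missing",
    "read_csv",
    "write_csv",
    "write_mask",
]


def compute_mask(values: np.ndarray) -> np.ndarray:
    """Binary observation indicator: 1 where a value is present, 0 where NaN."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError(f"expected a non-empty n x d matrix, got shape {values.shape}")
    return (~np.isnan(values)).astype(np.int8)


def compute_time_lag(timestamps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-attribute elapsed time since the last observation (the lag matrix)."""
    timestamps = np.asarray(timestamps, dtype=np.float64)
    mask = np.asarray(mask)
    if mask.ndim != 2 or timestamps.shape != (mask.shape[0],):
        raise ValueError("timestamps must be length n for an n x d mask")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n, d = mask.shape
    delta = np.zeros((n, d), dtype=np.float64)
    for t in range(1, n):
        gap = timestamps[t] - timestamps[t - 1]
        delta[t] = gap + delta[t - 1] * (1 - mask[t - 1])
    return delta


@dataclass
class TimeSeriesDataset:
    """Values, mask, timestamps and attribute names of one multivariate series."""

    values: np.ndarray
    mask: np.ndarray
    timestamps: np.ndarray
    attribute_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("need n >= 1 timestamps and d >= 1 attributes")
        if self.mask.shape != (n, d):
            raise ValueError("mask shape must match values")
        if self.timestamps.shape != (n,):
            raise ValueError("timestamps must have length n")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask entries must be 0 or 1")
        if len(self.attribute_names) != d:
            raise ValueError("need one attribute name per column")
        # mask is canonical: blank out anything it declares absent
        vals = self.values.copy()
        vals[self.mask == 0] = np.nan
        if np.isnan(vals[self.mask == 1]).any():
            raise ValueError("mask marks NaN entries as observed")
        self.values = vals

    @classmethod
    def from_values(cls, values, timestamps=None, attribute_names=None) -> "TimeSeriesDataset":
        """Build a dataset from a values matrix, inferring the mask from NaNs."""
        values = np.asarray(values, dtype=np.float64)
        mask = compute_mask(values)
        n, d = values.shape
        if timestamps is None:
            timestamps = np.arange(n, dtype=np.float64)
        if attribute_names is None:
            attribute_names = [f"attr_{j}" for j in range(d)]
        return cls(values, mask, timestamps, list(attribute_names))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def filled(self, fill_value: float = 0.0) -> np.ndarray:
        """Values with absent entries replaced by ``fill_value``."""
        out = self.values.copy()
        out[self.mask == 0] = fill_value
        return out

    def time_lag(self) -> np.ndarray:
        return compute_time_lag(self.timestamps, self.mask)

    def copy(self) -> "TimeSeriesDataset":
        return TimeSeriesDataset(self.values.copy(), self.mask.copy(),
                                 self.timestamps.copy(), list(self.attribute_names))


@dataclass
class Scaler:
    """Per-attribute min-max normalizer fitted on observed entries only.

    Attributes whose observed values are constant get zero range and are mapped
    to 0; inverting maps them back to the constant.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins

    def transform_values(self, values: np.ndarray) -> np.ndarray:
        rng = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (values - self.mins) / rng
        out = np.where(self.ranges > 0, out, 0.0)
        return np.where(np.isnan(values), np.nan, out)

    def invert_values(self, values: np.ndarray) -> np.ndarray:
        return values * self.ranges + self.mins


def fit_scaler(dataset: TimeSeriesDataset) -> Scaler:
    obs_counts = dataset.mask.sum(axis=0)
    if np.any(obs_counts == 0):
        bad = [dataset.attribute_names[j] for j in np.flatnonzero(obs_counts == 0)]
        raise ValueError(f"attributes with no observed entries: {bad}")
    mins = np.nanmin(dataset.values, axis=0)
    maxs = np.nanmax(dataset.values, axis=0)
    return Scaler(mins=mins, maxs=maxs)


def apply_scaler(dataset: TimeSeriesDataset, scaler: Scaler) -> TimeSeriesDataset:
    return TimeSeriesDataset(scaler.transform_values(dataset.values), dataset.mask.copy(),
                             dataset.timestamps.copy(), list(dataset.attribute_names))


def invert_scaler(dataset: TimeSeriesDataset, scaler: Scaler) -> TimeSeriesDataset:
    return TimeSeriesDataset(scaler.invert_values(dataset.values), dataset.mask.copy(),
                             dataset.timestamps.copy(), list(dataset.attribute_names))


def segment(dataset: TimeSeriesDataset, window_length: int) -> list[TimeSeriesDataset]:
    """Cut into consecutive non-overlapping windows.

    A trailing partial window is kept when it has at least two rows (the
    minimum a one-step-ahead model can use); a shorter remainder is dropped.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    windows = []
    for start in range(0, dataset.n, window_length):
        stop = min(start + window_length, dataset.n)
        if stop - start < 2:
            break
        windows.append(TimeSeriesDataset(
            dataset.values[start:stop].copy(), dataset.mask[start:stop].copy(),
            dataset.timestamps[start:stop].copy(), list(dataset.attribute_names)))
    return windows


def inject_missing(dataset: TimeSeriesDataset, p: float, seed: int
                   ) -> tuple[TimeSeriesDataset, np.ndarray]:
    """Drop ``round(p * n_observed)`` observed entries uniformly at random (MCAR).

    Returns the corrupted dataset and an eval mask marking exactly the dropped
    entries.  Already-missing cells are never re-dropped, so ground truth
    exists for every marked entry.
    """
    if not 0 <= p < 1:
        raise ValueError("drop fraction p must satisfy 0 <= p < 1")
    rng = np.random.default_rng(seed)
    obs_rows, obs_cols = np.nonzero(dataset.mask)
    k = int(np.rint(p * len(obs_rows)))
    eval_mask = np.zeros_like(dataset.mask)
    if k > 0:
        chosen = rng.choice(len(obs_rows), size=k, replace=False)
        eval_mask[obs_rows[chosen], obs_cols[chosen]] = 1
    new_mask = dataset.mask - eval_mask
    values = dataset.values.copy()
    values[eval_mask == 1] = np.nan
    corrupted = TimeSeriesDataset(values, new_mask, dataset.timestamps.copy(),
                                  list(dataset.attribute_names))
    return corrupted, eval_mask


# -- delimited-file interfaces ------------------------------------------------

def read_csv(path) -> TimeSeriesDataset:
    """Read a wide CSV (header of attribute names, empty cells = missing).

    A leading ``timestamp`` column (numeric or ISO-8601) supplies the time
    axis; otherwise timestamps default to the row index with unit spacing.
    """
    df = pd.read_csv(path)
    if df.columns[0].lower() == "timestamp":
        ts_raw = df.iloc[:, 0]
        df = df.iloc[:, 1:]
        ts_num = pd.to_numeric(ts_raw, errors="coerce")
        if ts_num.notna().all():
            timestamps = ts_num.to_numpy(dtype=np.float64)
        else:
            dt = pd.to_datetime(ts_raw)
            timestamps = (dt - dt.iloc[0]).dt.total_seconds().to_numpy()
    else:
        timestamps = np.arange(len(df), dtype=np.float64)
    values = df.to_numpy(dtype=np.float64)
    return TimeSeriesDataset(values, compute_mask(values), timestamps, list(df.columns))


def write_csv(dataset: TimeSeriesDataset, path) -> None:
    df = pd.DataFrame(dataset.values, columns=dataset.attribute_names)
    df.insert(0, "timestamp", dataset.timestamps)
    df.to_csv(path, index=False)


def write_mask(mask: np.ndarray, attribute_names: Sequence[str], path) -> None:
    pd.DataFrame(np.asarray(mask, dtype=int), columns=list(attribute_names)).to_csv(
        path, index=False)
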