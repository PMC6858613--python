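"""Cleaning and shaping of raw patient series.

Pipeline order: last-observation-carried-forward imputation, proportional
chronological train/validation/test splitting, per-feature min-max scaling to
[-1, 1] fitted on the training block only, and supervised sliding-window
construction (inputs: `lookback` days of all six features; target: the next
day's scaled glucose).

Missing values at the head of a series, where LOCF has nothing to carry
forward, are back-filled from the first observation so the series keeps its
length.  The scaler is fitted on training rows only, so validation/test
values may legitimately fall outside [-1, 1]; they are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glucoforecast.cohort import FEATURES, GLUCOSE, PatientSeries

#: Plausible physiologic range used when flagging outliers, mg/dL.
GLUCOSE_PLAUSIBLE = (40.0, 600.0)


@dataclass(frozen=True)
class SplitSpec:
    """Contiguous chronological split sizes (train earliest, test latest)."""

    train_days: int
    val_days: int
    test_days: int

    @property
    def n_days(self) -> int:
        return self.train_days + self.val_days + self.test_days

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.train_days, self.val_days, self.test_days)


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature min-max affine map onto [range_lo, range_hi].

    ``x' = (x - x_min) / (x_max - x_min) * (range_hi - range_lo) + range_lo``
    """

    x_min: np.ndarray  # shape (6,)
    x_max: np.ndarray  # shape (6,)
    range_lo: float = -1.0
    range_hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.range_lo < self.range_hi:
            raise ValueError("range_lo must be < range_hi")
        bad = np.asarray(self.x_max) <= np.asarray(self.x_min)
        if np.any(bad):
            names = [FEATURES[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"degenerate (constant) feature(s) in training rows: {names}")

    def glucose_span(self) -> float:
        """mg/dL per unit of scaled glucose (for converting scaled RMSE)."""
        return float(self.x_max[GLUCOSE] - self.x_min[GLUCOSE]) / (self.range_hi - self.range_lo)


@dataclass
class WindowedDataset:
    """Supervised (window, next-day glucose) pairs on the scaled series.

    inputs: (n, lookback, 6); targets: (n,) scaled glucose of the day after
    each window; day_indices: (n,) integer index of each target day within
    the full series.
    """

    inputs: np.ndarray
    targets: np.ndarray
    day_indices: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.targets)
        if self.inputs.shape[0] != n or self.day_indices.shape[0] != n:
            raise ValueError("inputs, targets and day_indices must align")

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def lookback(self) -> int:
        return self.inputs.shape[1]

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        return WindowedDataset(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.targets for p in parts]),
            np.concatenate([p.day_indices for p in parts]),
        )


def impute_locf(series: PatientSeries) -> PatientSeries:
    """Fill missing cells with the last observed value of the same feature.

    Head-of-series gaps are back-filled from the first observation.  The
    observed mask is preserved on the result for diagnostics.  Idempotent.
    """
    raw = series.masked_values()
    fully_missing = raw.columns[raw.isna().all()]
    if len(fully_missing):
        raise ValueError(
            f"patient {series.patient_id}: feature(s) fully missing: {list(fully_missing)}"
        )
    filled = raw.ffill().bfill()
    return PatientSeries(series.patient_id, filled, series.observed.copy(),
                         dict(series.metadata))


def flag_outliers(series: PatientSeries, winsorize: bool = False) -> tuple[PatientSeries, int]:
    """Flag (and optionally winsorize) implausible glucose readings.

    Returns the (possibly modified) series and the count of flagged cells.
    Default is flag-only: readings outside [40, 600] mg/dL are counted but
    left untouched.
    """
    lo, hi = GLUCOSE_PLAUSIBLE
    g = series.values["glucose_mgdl"]
    flagged = int(((g < lo) | (g > hi)).sum())
    if winsorize and flagged:
        out = series.copy()
        out.values["glucose_mgdl"] = g.clip(lo, hi)
        return out, flagged
    return series, flagged


def split_series(n_days: int) -> SplitSpec:
    """Proportional 120:30:30 chronological split.

    Validation and test each get ``n/6`` rounded to the nearest integer
    (ties up); training takes the remainder.  Reproduces the worked
    allocations 180 -> (120, 30, 30) and 41 -> (27, 7, 7).
    """
    if n_days < 6:
        raise ValueError(f"need at least 6 days to split, got {n_days}")
    side = int(np.floor(n_days / 6.0 + 0.5))  # round half up
    return SplitSpec(n_days - 2 * side, side, side)


def fit_scaler(
    series: PatientSeries,
    split: SplitSpec,
    range_lo: float = -1.0,
    range_hi: float = 1.0,
) -> ScalingParams:
    """Per-feature min/max from the training block only (leakage-free)."""
    if split.n_days != series.n_days:
        raise ValueError("split sizes must sum to the series length")
    train = series.values.iloc[: split.train_days]
    return ScalingParams(
        x_min=train.min().to_numpy(dtype=float),
        x_max=train.max().to_numpy(dtype=float),
        range_lo=range_lo,
        range_hi=range_hi,
    )


def scale(values: np.ndarray | pd.DataFrame, params: ScalingParams) -> np.ndarray:
    """Min-max scale an (n, 6) array (or a length-6 vector) of raw features."""
    x = np.asarray(values, dtype=float)
    span = params.x_max - params.x_min
    return (x - params.x_min) / span * (params.range_hi - params.range_lo) + params.range_lo


def inverse_scale(scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Exact inverse of :func:`scale`."""
    x = np.asarray(scaled, dtype=float)
    span = params.x_max - params.x_min
    return (x - params.range_lo) / (params.range_hi - params.range_lo) * span + params.x_min


def scale_glucose(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Scale glucose values (mg/dL) alone."""
    x = np.asarray(values, dtype=float)
    span = params.x_max[GLUCOSE] - params.x_min[GLUCOSE]
    return (x - params.x_min[GLUCOSE]) / span * (params.range_hi - params.range_lo) + params.range_lo


def inverse_scale_glucose(scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Map scaled glucose back to mg/dL."""
    x = np.asarray(scaled, dtype=float)
    span = params.x_max[GLUCOSE] - params.x_min[GLUCOSE]
    return (x - params.range_lo) / (params.range_hi - params.range_lo) * span + params.x_min[GLUCOSE]


def _window_block(
    scaled: np.ndarray, start: int, stop: int, lookback: int
) -> WindowedDataset:
    """Windows whose *targets* lie in [start, stop); context may reach back
    ``lookback`` days before ``start`` (into the previous split)."""
    inputs, targets, days = [], [], []
    for t in range(max(start, lookback), stop):
        inputs.append(scaled[t - lookback : t, :])
        targets.append(scaled[t, GLUCOSE])
        days.append(t)
    if not targets:
        shape = (0, lookback, scaled.shape[1])
        return WindowedDataset(np.empty(shape), np.empty(0), np.empty(0, dtype=int))
    return WindowedDataset(np.stack(inputs), np.asarray(targets), np.asarray(days))


def make_windows(
    series: PatientSeries,
    params: ScalingParams,
    split: SplitSpec,
    lookback: int = 1,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Build (train, val, test) supervised windows on the scaled series.

    Targets never cross split boundaries; validation and test windows may use
    up to ``lookback`` days of context from the preceding split, mirroring
    deployment (yesterday's data is always available).
    """
    if not 1 <= lookback < series.n_days:
        raise ValueError(f"lookback must be in [1, {series.n_days - 1}], got {lookback}")
    scaled = scale(series.values.to_numpy(dtype=float), params)
    a = split.train_days
    b = a + split.val_days
    c = b + split.test_days
    train = _window_block(scaled, 0, a, lookback)
    val = _window_block(scaled, a, b, lookback)
    test = _window_block(scaled, b, c, lookback)
    return train, val, test


@dataclass
class PreparedPatient:
    """Everything downstream stages need for one patient: the imputed series,
    its split, the training-fitted scaler, and the three window sets."""

    series: PatientSeries  # imputed
    split: SplitSpec
    scaler: ScalingParams
    train: WindowedDataset
    val: WindowedDataset
    test: WindowedDataset

    @property
    def patient_id(self) -> str:
        return self.series.patient_id

    def scaled_train_glucose(self) -> np.ndarray:
        """Scaled glucose over the training block (similarity comparisons)."""
        g = self.series.values["glucose_mgdl"].to_numpy()[: self.split.train_days]
        return scale_glucose(g, self.scaler)


def prepare_patient(series: PatientSeries, lookback: int = 1) -> PreparedPatient:
    """Impute, split, fit the scaler, and window one patient's series."""
    imputed = impute_locf(series)
    split = split_series(imputed.n_days)
    scaler = fit_scaler(imputed, split)
    train, val, test = make_windows(imputed, scaler, split, lookback=lookback)
    return PreparedPatient(imputed, split, scaler, train, val, test)


def preprocess_report(series: PatientSeries, split: SplitSpec) -> dict:
    """Counts of imputed cells per feature plus split sizes, as plain data."""
    imputed = (~series.observed).sum()
    return {
        "patient_id": series.patient_id,
        "n_days": series.n_days,
        "imputed_cells": {f: int(imputed[f]) for f in FEATURES},
        "split": {"train": split.train_days, "val": split.val_days, "test": split.test_days},
    }
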