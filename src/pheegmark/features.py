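"""Pharmacodynamic feature extraction from band-power curves.

Each curve y(t) is summarised by three scalars computed over a fixed
post-injection window (by default 49 minutes long, starting 2 minutes
after the injection, with t = 0 at the injection sample):

* **slope** (alpha-hat) and **intercept** (beta-hat): ordinary least
  squares fit of y(t) ~ alpha*t + beta with t in *minutes* relative to the
  injection, so the intercept is the extrapolated level at the moment of
  injection and the slope is the drug-driven trend in power units per
  minute;
* **mPower**: the arithmetic mean of y(t) over the same window — the
  classical grand-mean band power.

``build_feature_table`` runs smoothing -> outlier removal -> regression
over a whole dataset; ``assemble_feature_vectors`` pivots the table into
per-sample feature matrices (one row per strain x animal x channel), with
columns ordered day-major, then band in canonical order, then parameter
(slope, intercept, mPower) — 144 columns for the full 8-day x 9-band x
{slope, intercept} selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import OutlierReport, median_filter
from .spectral import BAND_ORDER, BandPowerDataset

__all__ = [
    "FitWindow",
    "fit_linear_trend",
    "mean_power",
    "build_feature_table",
    "FeatureMatrix",
    "assemble_feature_vectors",
    "PARAMETERS",
]

PARAMETERS: tuple[str, ...] = ("slope", "intercept", "mPower")


@dataclass(frozen=True)
class FitWindow:
    """Post-injection analysis window, half-open [start, start+length) minutes."""

    start_min: float = 2.0
    length_min: float = 49.0

    def __post_init__(self) -> None:
        if self.length_min <= 0:
            raise ValueError("fit window length must be positive")


DEFAULT_WINDOW = FitWindow()


def _window_mask(
    n_time: int, step_s: float, injection_index: int, window: FitWindow
) -> np.ndarray:
    t_min = (np.arange(n_time) - injection_index) * step_s / 60.0
    end = window.start_min + window.length_min
    # the window must be fully covered by the record
    if (injection_index + end * 60.0 / step_s) > n_time + 1e-9:
        raise ValueError(
            f"fit window [{window.start_min}, {end}) min after injection extends past "
            f"the record end ({n_time} samples at {step_s} s)"
        )
    mask = (t_min >= window.start_min) & (t_min < end)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 samples in the fit window")
    return mask


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS of y ~ a*t + b along the last axis of y."""
    t_mean = t.mean()
    tc = t - t_mean
    denom = (tc**2).sum()
    y_mean = y.mean(axis=-1)
    slope = (y * tc).sum(axis=-1) / denom
    intercept = y_mean - slope * t_mean
    return slope, intercept


def fit_linear_trend(
    series: np.ndarray,
    step_s: float,
    injection_index: int,
    window: FitWindow = DEFAULT_WINDOW,
) -> tuple[float, float]:
    """OLS (slope, intercept) of one curve over the post-injection window.

    The time axis is minutes relative to the injection sample, so the
    intercept is the fitted level at t = 0 (injection time) and the slope
    is in power units per minute.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D; use build_feature_table for datasets")
    mask = _window_mask(y.shape[0], step_s, injection_index, window)
    t_min = (np.nonzero(mask)[0] - injection_index) * step_s / 60.0
    slope, intercept = _ols_line(t_min, y[mask])
    return float(slope), float(intercept)


def mean_power(
    series: np.ndarray,
    step_s: float,
    injection_index: int,
    window: FitWindow = DEFAULT_WINDOW,
) -> float:
    """mPower: arithmetic mean of the curve over the same window as the fit."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    mask = _window_mask(y.shape[0], step_s, injection_index, window)
    return float(y[mask].mean())


def build_feature_table(
    dataset: BandPowerDataset,
    outlier_report: OutlierReport | None = None,
    smoothing_window: int | None = 241,
    window: FitWindow = DEFAULT_WINDOW,
    drop_outliers: bool = True,
) -> pd.DataFrame:
    """Slope/intercept/mPower for every curve of a dataset.

    Applies the median filter (unless ``smoothing_window`` is None), drops
    curves flagged in ``outlier_report`` (unless ``drop_outliers`` is
    False, mirroring analyses that keep outliers for visualisation), and
    fits every remaining curve.  Returns a long-format DataFrame with
    columns strain, animal, channel, day, band, slope, intercept, mPower.
    """
    power = dataset.power
    if smoothing_window is not None and smoothing_window > 1:
        power = median_filter(power, smoothing_window, axis=1)

    mask = _window_mask(dataset.n_time, dataset.step_s, dataset.injection_index, window)
    t_min = (np.nonzero(mask)[0] - dataset.injection_index) * dataset.step_s / 60.0

    y = power[:, mask]  # (band, Tw, channel, day, animal, strain)
    y = np.moveaxis(y, 1, -1)  # (band, channel, day, animal, strain, Tw)
    slope, intercept = _ols_line(t_min, y)
    mpow = y.mean(axis=-1)

    bands = dataset.band_names
    idx = pd.MultiIndex.from_product(
        [bands, dataset.channels, dataset.days, dataset.animals, dataset.strains],
        names=["band", "channel", "day", "animal", "strain"],
    )
    table = pd.DataFrame(
        {
            "slope": slope.ravel(),
            "intercept": intercept.ravel(),
            "mPower": mpow.ravel(),
        },
        index=idx,
    ).reset_index()
    table = table[["strain", "animal", "channel", "day", "band",
                   "slope", "intercept", "mPower"]]

    if outlier_report is not None and drop_outliers:
        flagged = outlier_report.table.loc[outlier_report.table["flagged"]]
        key_cols = ["strain", "animal", "channel", "day", "band"]
        bad = set(map(tuple, flagged[key_cols].itertuples(index=False)))
        keep = ~table[key_cols].apply(tuple, axis=1).isin(bad)
        table = table.loc[keep].reset_index(drop=True)
    return table


@dataclass
class FeatureMatrix:
    """Samples x features matrix with explicit row/column bookkeeping."""

    X: np.ndarray
    feature_index: list[tuple[str, str, str]]  # (day, band, parameter)
    sample_index: list[tuple[str, str, str]]  # (strain, animal, channel)
    y: np.ndarray  # strain label per row
    dropped: list[tuple[str, str, str]]  # samples removed for missing cells


def assemble_feature_vectors(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("slope", "intercept"),
    days: tuple[str, ...] | None = None,
    bands: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Pivot the feature table into one row per (strain, animal, channel).

    Column order is day-major, then band in canonical order, then
    parameter in (slope, intercept, mPower) order.  Rows missing any
    requested cell (e.g. removed as outliers) are dropped and reported in
    ``FeatureMatrix.dropped``.
    """
    if not parameters:
        raise ValueError("empty parameter selection")
    bad = set(parameters) - set(PARAMETERS)
    if bad:
        raise ValueError(f"unknown parameters {sorted(bad)}; valid: {PARAMETERS}")
    parameters = tuple(p for p in PARAMETERS if p in parameters)

    all_days = sorted(table["day"].unique())
    present_bands = set(table["band"].unique())
    all_bands = [b for b in BAND_ORDER if b in present_bands]
    all_bands += sorted(present_bands - set(all_bands))
    days = tuple(days) if days is not None else tuple(all_days)
    bands = tuple(bands) if bands is not None else tuple(all_bands)
    if not days or not bands:
        raise ValueError("empty day or band selection")
    for d in days:
        if d not in all_days:
            raise ValueError(f"day {d!r} absent from the feature table")
    for b in bands:
        if b not in present_bands:
            raise ValueError(f"band {b!r} absent from the feature table")

    sub = table[table["day"].isin(days) & table["band"].isin(bands)]
    wide = sub.pivot_table(
        index=["strain", "animal", "channel"],
        columns=["day", "band"],
        values=list(parameters),
        aggfunc="first",
    )

    feature_index: list[tuple[str, str, str]] = [
        (d, b, p) for d in days for b in bands for p in parameters
    ]
    cols = [(p, d, b) for (d, b, p) in feature_index]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))

    complete = wide.notna().all(axis=1)
    dropped = [tuple(map(str, k)) for k in wide.index[~complete]]
    wide = wide.loc[complete]

    X = wide.to_numpy(dtype=float)
    sample_index = [tuple(map(str, k)) for k in wide.index]
    y = np.array([s for (s, _, _) in sample_index])
    return FeatureMatrix(
        X=X, feature_index=feature_index, sample_index=sample_index, y=y, dropped=dropped
    )
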