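"""Wrist-actigraphy feature extraction over consecutive 24-h windows.

Per-minute activity counts are split into 24-h windows anchored at ICU
admission; each window yields nine statistics (fixed column order):
minimum, maximum, mean, variance, standard deviation, immobile fraction,
IQR, RMSSD, and the between-hour SD of RMSSD. Sample statistics use ddof=1;
percentile-based statistics interpolate linearly. Windows too short for a
statistic leave a NaN cell, which the preprocessing machinery later imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ACTIVITY_FEATURE_NAMES = [
    "minimum",
    "maximum",
    "mean",
    "variance",
    "sd",
    "immobile_fraction",
    "iqr",
    "rmssd",
    "rmssd_sd",
]

EPOCHS_PER_DAY = 24 * 60  # 1-minute epochs


class FeatureUndefinedError(ValueError):
    """A statistic is undefined for the given window (too few epochs)."""


def window_24h(
    counts: np.ndarray, epochs_per_window: int = EPOCHS_PER_DAY, min_epochs: int = 2
) -> list[np.ndarray]:
    """Split admission-anchored epoch counts into consecutive 24-h windows.

    A trailing partial window is kept only if it has at least ``min_epochs``
    epochs. An empty series yields an empty list.
    """
    counts = np.asarray(counts)
    windows = [
        counts[i : i + epochs_per_window]
        for i in range(0, len(counts), epochs_per_window)
    ]
    if windows and len(windows[-1]) < min_epochs:
        windows.pop()
    return windows


def rmssd(x: np.ndarray) -> float:
    """Root mean square of successive differences: sqrt(mean((x[i+1]-x[i])^2))."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise FeatureUndefinedError("RMSSD needs at least 2 epochs")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def immobile_fraction(x: np.ndarray, threshold: float = 0.0) -> float:
    """Fraction of epochs with count at or below ``threshold``."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise FeatureUndefinedError("immobile fraction needs at least 1 epoch")
    return float(np.mean(x <= threshold))


def rmssd_sd(x: np.ndarray, subwindow_epochs: int = 60) -> float:
    """Sample SD (ddof=1) of per-sub-window RMSSD values.

    The window is partitioned into consecutive complete sub-windows of
    ``subwindow_epochs`` epochs (one hour at minute epochs); a trailing
    incomplete sub-window is dropped. Fewer than two complete sub-windows is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    n_sub = x.size // subwindow_epochs
    if n_sub < 2:
        raise FeatureUndefinedError(
            "SD of RMSSD needs at least 2 complete sub-windows"
        )
    vals = [rmssd(x[i * subwindow_epochs : (i + 1) * subwindow_epochs]) for i in range(n_sub)]
    return float(np.std(vals, ddof=1))


def extract_features(
    window: np.ndarray, immobile_threshold: float = 0.0, subwindow_epochs: int = 60
) -> np.ndarray:
    """The nine window statistics in fixed order; undefined cells are NaN."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise FeatureUndefinedError("feature window needs at least 2 epochs")
    out = np.empty(len(ACTIVITY_FEATURE_NAMES))
    out[0] = x.min()
    out[1] = x.max()
    out[2] = x.mean()
    out[3] = x.var(ddof=1)
    out[4] = x.std(ddof=1)
    out[5] = immobile_fraction(x, immobile_threshold)
    q25, q75 = np.percentile(x, [25.0, 75.0])
    out[6] = q75 - q25
    out[7] = rmssd(x)
    try:
        out[8] = rmssd_sd(x, subwindow_epochs)
    except FeatureUndefinedError:
        out[8] = np.nan
    return out


@dataclass
class ActivityFeatureMatrix:
    """Daily actigraphy features for one stay: days x 9 with an observed mask."""

    stay_id: str
    values: np.ndarray  # (days, 9), NaN where undefined
    mask: np.ndarray  # (days, 9) bool
    window_starts: list  # window start timestamps

    feature_names = ACTIVITY_FEATURE_NAMES


def activity_feature_matrix(
    activity: pd.DataFrame,
    admit_time: pd.Timestamp,
    stay_id: str = "",
    immobile_threshold: float = 0.0,
    subwindow_epochs: int = 60,
) -> ActivityFeatureMatrix:
    """Windowed feature matrix from a per-minute activity table (time, count)."""
    counts = np.asarray(activity["count"], dtype=float)
    windows = window_24h(counts)
    rows = [
        extract_features(w, immobile_threshold, subwindow_epochs) for w in windows
    ]
    values = np.vstack(rows) if rows else np.empty((0, len(ACTIVITY_FEATURE_NAMES)))
    starts = [admit_time + pd.Timedelta(hours=24 * d) for d in range(len(windows))]
    return ActivityFeatureMatrix(
        stay_id=stay_id, values=values, mask=~np.isnan(values), window_starts=starts
    )


def features_to_frame(mat: ActivityFeatureMatrix) -> pd.DataFrame:
    """Flat days x 9 table with a window_start column (CSV/Parquet-ready)."""
    df = pd.DataFrame(mat.values, columns=ACTIVITY_FEATURE_NAMES)
    df.insert(0, "window_start", mat.window_starts)
    df.insert(0, "stay_id", mat.stay_id)
    return df
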