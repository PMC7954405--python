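"""Hourly resampling, percentile capping, imputation, and standardization.

Raw timestamped vital-sign records are binned to a fixed 1-h grid anchored at
ICU admission (half-open bins, in-bin arithmetic mean). Per-feature statistics
— 1st/99th-percentile caps, imputation median, standardization mean/SD — are
fitted on a development set only and then applied to any stay: cap, forward-
fill (leading gaps take the dev median), z-score. The same fit/apply machinery
serves both the 6 hourly vitals and the 9 daily actigraphy features.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from icu_acuity.cohort import VITAL_NAMES

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class VitalsMatrix:
    """Hourly vitals for one stay: hours x 6 values with an observed mask.

    Unobserved cells carry NaN (never a silent zero); column order is
    ``VITAL_NAMES`` (dbp, sbp, heart_rate, resp_rate, spo2, temp).
    """

    stay_id: str
    values: np.ndarray  # (hours, 6), NaN where unobserved
    mask: np.ndarray  # (hours, 6) bool, True = observed


def resample_hourly(
    records: pd.DataFrame,
    admit_time: pd.Timestamp,
    discharge_time: pd.Timestamp,
    stay_id: str = "",
) -> VitalsMatrix:
    """Bin timestamped records to the stay's hourly grid (mean within bin).

    Hour bin h covers [admit + h, admit + h+1) hours. Records outside
    [admit, discharge] — or falling past the last bin — are rejected with a
    logged warning. Empty bins are masked unobserved.
    """
    duration_h = (discharge_time - admit_time) / pd.Timedelta(hours=1)
    n_hours = int(math.ceil(duration_h))
    values = np.full((n_hours, len(VITAL_NAMES)), np.nan)
    if len(records):
        t = pd.to_datetime(records["time"])
        bins = np.floor(
            (t - admit_time) / pd.Timedelta(hours=1)
        ).astype(int).to_numpy()
        in_window = (t >= admit_time) & (t <= discharge_time) & (bins < n_hours) & (bins >= 0)
        n_bad = int((~in_window).sum())
        if n_bad:
            logger.warning(
                "stay %s: rejected %d record(s) outside the stay window", stay_id, n_bad
            )
        keep = in_window.to_numpy()
        col_of = {name: j for j, name in enumerate(VITAL_NAMES)}
        cols = records["variable"].map(col_of).to_numpy(dtype=float)
        keep &= ~np.isnan(cols)
        b_arr = bins[keep]
        c_arr = cols[keep].astype(int)
        v_arr = records["value"].to_numpy(dtype=float)[keep]
        flat = b_arr * len(VITAL_NAMES) + c_arr
        sums = np.bincount(flat, weights=v_arr, minlength=n_hours * len(VITAL_NAMES))
        cnts = np.bincount(flat, minlength=n_hours * len(VITAL_NAMES))
        with np.errstate(invalid="ignore"):
            means = sums / cnts
        values = means.reshape(n_hours, len(VITAL_NAMES))
    mask = ~np.isnan(values)
    return VitalsMatrix(stay_id=stay_id, values=values, mask=mask)


@dataclass
class PreprocessStats:
    """Per-feature cap bounds, imputation median, and standardization constants.

    Fitted on a development pool of observed values; ``mean``/``sd`` are
    computed after capping so that capping + z-scoring of the dev pool is
    exactly zero-mean/unit-SD. Degenerate (constant) features get sd = 1.
    """

    feature_names: list[str]
    p01: np.ndarray
    p99: np.ndarray
    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            **{
                k: getattr(self, k).tolist()
                for k in ("p01", "p99", "median", "mean", "sd")
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PreprocessStats":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            **{k: np.asarray(d[k], dtype=float) for k in ("p01", "p99", "median", "mean", "sd")},
        )


def fit_preprocess_stats(
    matrices: Sequence, feature_names: Sequence[str] | None = None
) -> PreprocessStats:
    """Fit caps/median/mean/SD from the observed cells of development matrices.

    Accepts any objects with ``values``/``mask`` arrays of equal width
    (VitalsMatrix or activity-feature matrices). Percentiles use linear
    interpolation between order statistics; mean/SD (ddof=0) are computed on
    the pooled values after capping.
    """
    if not matrices:
        raise PreprocessError("need at least one development matrix")
    n_feat = matrices[0].values.shape[1]
    if feature_names is None:
        feature_names = getattr(matrices[0], "feature_names", None) or (
            VITAL_NAMES if n_feat == len(VITAL_NAMES) else [f"f{j}" for j in range(n_feat)]
        )
    p01 = np.empty(n_feat)
    p99 = np.empty(n_feat)
    median = np.empty(n_feat)
    mean = np.empty(n_feat)
    sd = np.empty(n_feat)
    for j in range(n_feat):
        pool = np.concatenate([m.values[m.mask[:, j], j] for m in matrices])
        if pool.size == 0:
            raise PreprocessError(
                f"feature '{feature_names[j]}' has no observed values in the development set"
            )
        p01[j], p99[j] = np.percentile(pool, [1.0, 99.0])
        capped = np.clip(pool, p01[j], p99[j])
        median[j] = np.median(capped)
        mean[j] = capped.mean()
        s = capped.std(ddof=0)
        sd[j] = s if s > 1e-12 else 1.0
    return PreprocessStats(
        feature_names=list(feature_names), p01=p01, p99=p99, median=median, mean=mean, sd=sd
    )


def apply_preprocess(
    values: np.ndarray, mask: np.ndarray, stats: PreprocessStats
) -> np.ndarray:
    """Cap, forward-fill-impute, and standardize one stay's matrix.

    Per feature column: (1) observed values are clipped into [p01, p99];
    (2) unobserved cells take the most recent observed (post-clip) value in
    the stay, with leading gaps set to the dev median; (3) everything is
    z-scored with the dev mean/SD. The output has the input shape and no
    missing cells.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape or values.shape[1] != len(stats.feature_names):
        raise PreprocessError(
            f"shape mismatch: matrix {values.shape} vs {len(stats.feature_names)} fitted features"
        )
    capped = np.clip(values, stats.p01[None, :], stats.p99[None, :])
    capped = np.where(mask, capped, np.nan)
    # vectorized forward fill down each column
    n = values.shape[0]
    idx = np.where(mask, np.arange(n)[:, None], -1)
    idx = np.maximum.accumulate(idx, axis=0)
    filled = np.where(
        idx >= 0,
        np.take_along_axis(np.where(mask, capped, 0.0), np.maximum(idx, 0), axis=0),
        stats.median[None, :],
    )
    return (filled - stats.mean[None, :]) / stats.sd[None, :]
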