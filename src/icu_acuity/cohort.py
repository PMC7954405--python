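"""Synthetic ICU cohort generator.

Emulates the statistical structure of two ICU cohorts: a large "source"
cohort carrying only routinely charted vital signs, and a small "target"
cohort additionally monitored with a wrist-worn activity sensor. A latent
hourly severity process drives (a) shifts in six vital signs, (b) suppression
of wrist activity, and (c) the probability of an unsuccessful hospital
discharge, so that downstream models have a recoverable signal whose strength
is set by two effect dials.

The generative distributions are artifact choices (the real cohorts are
restricted); magnitudes are anchored to typical ICU summary statistics:
cohort vital-sign medians near (DBP 62, SBP 122, HR 88, RR 18.5, SpO2 97,
Temp 37.0) and minute-epoch activity counts dominated by immobility
(mean count ~3, immobile fraction ~0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

VITAL_NAMES = ["dbp", "sbp", "heart_rate", "resp_rate", "spo2", "temp"]

# name -> (baseline, per-unit-severity shift, within-hour noise SD,
#          between-patient baseline SD)
# Signs: sicker patients run tachycardic, tachypneic, febrile, hypotensive,
# and desaturated. The patient-level baseline offsets are independent of
# severity: they confound any single vital sign, so recovering severity
# requires weighing all six jointly (as in real cohorts).
VITAL_SPECS = {
    "dbp": (62.0, -3.5, 7.0, 6.0),
    "sbp": (122.0, -6.5, 11.0, 10.0),
    "heart_rate": (88.0, 6.0, 8.0, 7.0),
    "resp_rate": (18.5, 2.0, 2.5, 2.0),
    "spo2": (97.0, -1.2, 1.5, 1.0),
    "temp": (37.0, 0.25, 0.35, 0.25),
}

# Zero-inflated activity model: P(immobile minute) = logistic(a0 + b_i +
# effect * s) with a patient-level mobility offset b_i; active-minute counts
# are 1 + NegBin with severity-suppressed mean.
IMMOBILE_INTERCEPT = float(logit(0.6))
ACTIVE_MEAN_BASE = 7.0  # mean count of an active minute at severity 0
ACTIVE_MEAN_SUPPRESSION = 0.5  # log-scale decline per unit severity
ACTIVE_NB_DISPERSION = 1.2
ACTIVITY_LEVEL_SD = 0.6  # SD of the patient mobility offset (logit scale)


class CohortConfigError(ValueError):
    """Raised for invalid cohort configurations."""


class InvalidStayError(ValueError):
    """Raised when a stay violates the minimum-duration contract."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the small multi-modal target cohort; see
    :func:`source_cohort_config` for the large vitals-only source cohort.
    """

    n_stays: int = 51
    prevalence_unsuccessful: float = 0.35
    include_activity: bool = True
    los_log_mean: float = math.log(72.0)  # median stay 3 days
    los_log_sd: float = 0.35
    vitals_effect: float = 1.0
    activity_effect: float = 1.0
    missing_rate: float = 0.15
    noise_scale: float = 1.0  # scales record noise and patient baseline offsets
    seed: int = 0
    # latent severity dynamics (hourly Ornstein-Uhlenbeck)
    theta: float = 0.10
    vol: float = 0.30
    link_slope: float = 2.0
    admission_window_days: int = 730
    admission_start: str = "2021-01-01"
    max_los_hours: int = 720

    def __post_init__(self) -> None:
        if self.n_stays < 2:
            raise CohortConfigError("n_stays must be >= 2")
        if not 0.0 < self.prevalence_unsuccessful < 1.0:
            raise CohortConfigError("prevalence_unsuccessful must lie in (0, 1)")
        if self.vitals_effect < 0 or self.activity_effect < 0:
            raise CohortConfigError("effect sizes must be nonnegative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise CohortConfigError("missing_rate must lie in [0, 1]")
        if self.los_log_sd < 0 or self.vol <= 0 or not 0 < self.theta < 1:
            raise CohortConfigError("invalid severity/LOS dynamics parameters")


def source_cohort_config(n_stays: int = 2000, seed: int = 0, **overrides) -> CohortConfig:
    """Config for the large vitals-only source cohort (shorter stays, 25% prevalence)."""
    base = CohortConfig(
        n_stays=n_stays,
        prevalence_unsuccessful=0.25,
        include_activity=False,
        los_log_mean=math.log(48.0),
        los_log_sd=0.45,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def target_cohort_config(n_stays: int = 51, seed: int = 1, **overrides) -> CohortConfig:
    """Config for the small multi-modal target cohort."""
    base = CohortConfig(n_stays=n_stays, seed=seed)
    return replace(base, **overrides) if overrides else base


@dataclass
class ICUStay:
    """One intensive-care episode with raw measurement streams."""

    stay_id: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    vitals: pd.DataFrame  # columns: time, variable, value
    activity: Optional[pd.DataFrame]  # columns: time, count; None if not monitored
    label: int  # 1 = unsuccessful hospital discharge
    severity: np.ndarray = field(default=None, repr=False)  # hourly latent path

    @property
    def los_hours(self) -> int:
        return int(round((self.discharge_time - self.admit_time) / pd.Timedelta(hours=1)))


def severity_path(
    los_hours: int,
    theta: float,
    vol: float,
    rng: np.random.Generator,
    mu: Optional[float] = None,
    s0: Optional[float] = None,
) -> np.ndarray:
    """Hourly latent severity: discrete Ornstein-Uhlenbeck around a patient level.

    s_{t+1} = s_t + theta * (mu - s_t) + vol * eps_t with standard normal eps.
    ``mu`` is the patient's long-run severity level, drawn N(0, 1) when not
    given; the path starts at ``s0`` (default: one noisy step off ``mu``).
    Deviations from ``mu`` follow an AR(1) with lag-1 coefficient (1 - theta).
    """
    if los_hours < 24:
        raise InvalidStayError(f"stay must span >= 24 h, got {los_hours}")
    if mu is None:
        mu = float(rng.normal())
    if s0 is None:
        s0 = mu + vol * float(rng.normal())
    eps = rng.normal(size=los_hours - 1)
    s = np.empty(los_hours)
    s[0] = s0
    for t in range(los_hours - 1):
        s[t + 1] = s[t] + theta * (mu - s[t]) + vol * eps[t]
    return s


def emit_vitals(
    severity: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Irregular timestamped vital-sign records driven by the severity path.

    Per hour and vital, with probability ``1 - missing_rate``, 1-3 records are
    emitted at random minute offsets; values are the vital's baseline plus a
    patient-level offset (drawn here when not given), shifted by
    ``vitals_effect`` times the hourly severity, plus Gaussian record noise.
    Returned times are minute offsets from admission (``offset_min``).
    """
    if patient_offsets is None:
        patient_offsets = rng.normal(size=len(VITAL_NAMES)) * np.array(
            [VITAL_SPECS[n][3] for n in VITAL_NAMES]
        ) * config.noise_scale
    # decompensation response: vitals react disproportionately once severity
    # exceeds ~0.5 SD above the cohort mean
    sev_response = severity + 0.6 * np.maximum(severity - 0.5, 0.0)
    hours = len(severity)
    rows_off, rows_var, rows_val = [], [], []
    for v_idx, name in enumerate(VITAL_NAMES):
        base, coef, noise_sd, _ = VITAL_SPECS[name]
        observed = rng.random(hours) >= config.missing_rate
        n_rec = rng.integers(1, 4, size=hours)
        n_rec[~observed] = 0
        total = int(n_rec.sum())
        if total == 0:
            continue
        hour_idx = np.repeat(np.arange(hours), n_rec)
        minutes = hour_idx * 60 + rng.integers(0, 60, size=total)
        values = (
            base
            + patient_offsets[v_idx]
            + coef * config.vitals_effect * sev_response[hour_idx]
            + rng.normal(0.0, noise_sd * config.noise_scale, size=total)
        )
        if name == "spo2":
            values = np.minimum(values, 100.0)
        rows_off.append(minutes)
        rows_var.append(np.full(total, name, dtype=object))
        rows_val.append(values)
    if not rows_off:
        return pd.DataFrame({"offset_min": [], "variable": [], "value": []})
    df = pd.DataFrame(
        {
            "offset_min": np.concatenate(rows_off),
            "variable": np.concatenate(rows_var),
            "value": np.concatenate(rows_val),
        }
    )
    return df.sort_values(["offset_min", "variable"], kind="stable").reset_index(drop=True)


def immobility_probability(
    severity: np.ndarray, config: CohortConfig, level_offset: float = 0.0
) -> np.ndarray:
    """Per-minute immobility probability (severity step-held from hours to minutes)."""
    s_min = np.repeat(severity, 60)
    return expit(IMMOBILE_INTERCEPT + level_offset + config.activity_effect * s_min)


def emit_activity(
    severity: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    level_offset: float | None = None,
) -> np.ndarray:
    """Per-minute wrist activity counts: zero-inflated, immobility-dominated.

    A minute is immobile (count 0) with probability
    logistic(a0 + b + activity_effect * s), where b is a patient-level
    mobility offset (drawn here when not given); otherwise the count is
    1 + NegBin with mean declining in severity and mobility, so zero counts
    correspond exactly to immobile minutes.
    """
    if level_offset is None:
        level_offset = float(rng.normal(0.0, ACTIVITY_LEVEL_SD * config.noise_scale))
    p_imm = immobility_probability(severity, config, level_offset)
    n_min = p_imm.size
    immobile = rng.random(n_min) < p_imm
    s_min = np.repeat(severity, 60)
    mean_active = np.maximum(
        ACTIVE_MEAN_BASE
        * np.exp(
            -0.3 * level_offset
            - ACTIVE_MEAN_SUPPRESSION * config.activity_effect * s_min
        )
        - 1.0,
        0.05,
    )
    r = ACTIVE_NB_DISPERSION
    p_nb = r / (r + mean_active)
    counts = 1 + rng.negative_binomial(r, p_nb, size=n_min)
    counts[immobile] = 0
    return counts.astype(np.int64)


def assign_label(
    severity: np.ndarray,
    link_intercept: float,
    link_slope: float,
    rng: np.random.Generator,
) -> int:
    """Bernoulli discharge label from the mean of the final 24 h of severity."""
    m = float(np.mean(severity[-24:]))
    p = float(expit(link_intercept + link_slope * m))
    return int(rng.random() < p)


def calibrate_link_intercept(
    terminal_means: np.ndarray, link_slope: float, prevalence: float
) -> float:
    """Intercept a such that mean_i logistic(a + slope * m_i) = prevalence."""
    lo, hi = -30.0, 30.0

    def gap(a: float) -> float:
        return float(np.mean(expit(a + link_slope * terminal_means))) - prevalence

    return float(brentq(gap, lo, hi, xtol=1e-10))


def generate_cohort(config: CohortConfig) -> list[ICUStay]:
    """Generate a fully reproducible synthetic cohort.

    Admission times are spread uniformly over a multi-year calendar window so a
    chronological holdout is meaningful. The label-link intercept is calibrated
    on the cohort's realized severity so empirical prevalence tracks
    ``prevalence_unsuccessful``.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.admission_start)

    los = np.exp(rng.normal(config.los_log_mean, config.los_log_sd, config.n_stays))
    los_hours = np.clip(np.round(los).astype(int), 24, config.max_los_hours)
    admit_minutes = rng.integers(
        0, config.admission_window_days * 24 * 60, size=config.n_stays
    )
    severities = [
        severity_path(int(h), config.theta, config.vol, rng) for h in los_hours
    ]
    terminal_means = np.array([s[-24:].mean() for s in severities])
    intercept = calibrate_link_intercept(
        terminal_means, config.link_slope, config.prevalence_unsuccessful
    )

    stays: list[ICUStay] = []
    for i in range(config.n_stays):
        admit = start + pd.Timedelta(minutes=int(admit_minutes[i]))
        discharge = admit + pd.Timedelta(hours=int(los_hours[i]))
        sev = severities[i]
        label = assign_label(sev, intercept, config.link_slope, rng)
        vit = emit_vitals(sev, config, rng)
        vitals = pd.DataFrame(
            {
                "time": admit + pd.to_timedelta(vit["offset_min"].to_numpy(), unit="m"),
                "variable": vit["variable"].to_numpy(),
                "value": vit["value"].to_numpy(),
            }
        )
        activity = None
        if config.include_activity:
            counts = emit_activity(sev, config, rng)
            activity = pd.DataFrame(
                {
                    "time": admit + pd.to_timedelta(np.arange(counts.size), unit="m"),
                    "count": counts,
                }
            )
        stays.append(
            ICUStay(
                stay_id=f"stay{i:05d}",
                admit_time=admit,
                discharge_time=discharge,
                vitals=vitals,
                activity=activity,
                label=label,
                severity=sev,
            )
        )
    return stays


# ---------------------------------------------------------------------------
# Long-format table interchange (CSV / Parquet)
# ---------------------------------------------------------------------------


def cohort_tables(stays: list[ICUStay]) -> dict[str, pd.DataFrame]:
    """Long-format tables: vitals, activity (may be empty), and stay-level labels."""
    vitals = pd.concat(
        [s.vitals.assign(stay_id=s.stay_id) for s in stays], ignore_index=True
    )[["stay_id", "time", "variable", "value"]]
    act_frames = [
        s.activity.assign(stay_id=s.stay_id) for s in stays if s.activity is not None
    ]
    activity = (
        pd.concat(act_frames, ignore_index=True)[["stay_id", "time", "count"]]
        if act_frames
        else pd.DataFrame({"stay_id": [], "time": [], "count": []})
    )
    labels = pd.DataFrame(
        {
            "stay_id": [s.stay_id for s in stays],
            "admit_time": [s.admit_time for s in stays],
            "discharge_time": [s.discharge_time for s in stays],
            "label": [s.label for s in stays],
        }
    )
    return {"vitals": vitals, "activity": activity, "labels": labels}


def write_cohort(stays: list[ICUStay], outdir: str | Path, fmt: str = "csv") -> None:
    """Write the cohort's three long-format tables as CSV or Parquet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in cohort_tables(stays).items():
        path = outdir / f"{name}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "parquet":
            df.to_parquet(path, index=False)
        else:
            raise ValueError(f"unknown table format: {fmt}")


def read_cohort(indir: str | Path, fmt: str = "csv") -> list[ICUStay]:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)

    def load(name: str) -> pd.DataFrame:
        path = indir / f"{name}.{fmt}"
        if fmt == "csv":
            df = pd.read_csv(path)
        else:
            df = pd.read_parquet(path)
        for col in ("time", "admit_time", "discharge_time"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        return df

    vitals, activity, labels = load("vitals"), load("activity"), load("labels")
    vit_by = {k: g.drop(columns="stay_id") for k, g in vitals.groupby("stay_id")}
    act_by = {k: g.drop(columns="stay_id") for k, g in activity.groupby("stay_id")}
    stays = []
    for row in labels.itertuples(index=False):
        act = act_by.get(row.stay_id)
        stays.append(
            ICUStay(
                stay_id=row.stay_id,
                admit_time=row.admit_time,
                discharge_time=row.discharge_time,
                vitals=vit_by.get(
                    row.stay_id,
                    pd.DataFrame({"time": [], "variable": [], "value": []}),
                ).reset_index(drop=True),
                activity=act.reset_index(drop=True) if act is not None else None,
                label=int(row.label),
            )
        )
    return stays
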