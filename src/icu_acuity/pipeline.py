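"""Per-fold fit/score pipeline tying preprocessing to the GRU models.

Stat-free transformations (hourly resampling, actigraphy windowing) are done
once per cohort by :func:`prepare_stays`. Everything that is fitted —
percentile caps, imputation medians, standardization constants, model
parameters, the early-stopping carve-out — is fitted inside
``DischargePipeline.fit`` on the development stays it receives, so repeated
cross-validation never leaks held-out information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from icu_acuity.activity import ACTIVITY_FEATURE_NAMES, ActivityFeatureMatrix, activity_feature_matrix
from icu_acuity.cohort import VITAL_NAMES, ICUStay
from icu_acuity.models import (
    ModelConfig,
    StayTensors,
    build_parallel_rnn,
    build_single_rnn,
    train,
)
from icu_acuity.preprocess import (
    PreprocessStats,
    VitalsMatrix,
    apply_preprocess,
    fit_preprocess_stats,
    resample_hourly,
)
from icu_acuity.transfer import TransferSpec, initialize_from_source


@dataclass
class StayData:
    """One stay's stat-free intermediate representation."""

    stay_id: str
    admit_time: object
    label: int
    vitals: VitalsMatrix
    activity: Optional[ActivityFeatureMatrix]


def prepare_stay(stay: ICUStay) -> StayData:
    vit = resample_hourly(stay.vitals, stay.admit_time, stay.discharge_time, stay.stay_id)
    act = None
    if stay.activity is not None:
        act = activity_feature_matrix(stay.activity, stay.admit_time, stay.stay_id)
    return StayData(
        stay_id=stay.stay_id,
        admit_time=stay.admit_time,
        label=stay.label,
        vitals=vit,
        activity=act,
    )


def prepare_stays(stays: Sequence[ICUStay]) -> list[StayData]:
    return [prepare_stay(s) for s in stays]


class DischargePipeline:
    """Fit preprocessing statistics and a GRU model on development stays only."""

    def __init__(
        self,
        use_activity: bool,
        model_config: ModelConfig,
        source_checkpoint: Optional[dict[str, np.ndarray]] = None,
        transfer_spec: Optional[TransferSpec] = None,
    ):
        self.use_activity = use_activity
        self.model_config = model_config
        self.source_checkpoint = source_checkpoint
        self.transfer_spec = transfer_spec or TransferSpec()
        self.vitals_stats: Optional[PreprocessStats] = None
        self.activity_stats: Optional[PreprocessStats] = None
        self.model = None
        self.history = None
        self.transfer_audit = None

    def _tensors(self, stay: StayData) -> StayTensors:
        inputs = {
            "ehr": apply_preprocess(
                stay.vitals.values, stay.vitals.mask, self.vitals_stats
            ).astype(np.float32)
        }
        if self.use_activity:
            if stay.activity is None:
                raise ValueError(
                    f"stay {stay.stay_id!r} has no activity series but the "
                    "multi-modal pipeline requires one"
                )
            inputs["act"] = apply_preprocess(
                stay.activity.values, stay.activity.mask, self.activity_stats
            ).astype(np.float32)
        return StayTensors(inputs=inputs, label=stay.label, stay_id=stay.stay_id)

    def fit(self, dev_stays: Sequence[StayData], rng: np.random.Generator) -> "DischargePipeline":
        self.vitals_stats = fit_preprocess_stats(
            [s.vitals for s in dev_stays], VITAL_NAMES
        )
        if self.use_activity:
            self.activity_stats = fit_preprocess_stats(
                [s.activity for s in dev_stays], ACTIVITY_FEATURE_NAMES
            )
        data = [self._tensors(s) for s in dev_stays]
        if self.use_activity:
            self.model = build_parallel_rnn(config=self.model_config, rng=rng)
        else:
            self.model = build_single_rnn(config=self.model_config, rng=rng)
        if self.source_checkpoint is not None:
            self.transfer_audit = initialize_from_source(
                self.model, self.source_checkpoint, self.transfer_spec
            )
        self.history = train(self.model, data, self.model_config, rng=rng)
        return self

    def score(self, stays: Sequence[StayData]) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline must be fitted before scoring")
        return np.array([self.model.predict(self._tensors(s))[0] for s in stays])
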