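"""Partial-weight transfer learning from the large vitals-only cohort.

A single-branch GRU is pretrained on the chronological development portion of
the source cohort. Its recurrent weights and biases (the ``ehr.*`` parameter
group) initialize the EHR branch of a target-cohort model; the activity
branch and the prediction head keep their random initialization (head
transfer is possible behind a flag, and only shape-legal for the vitals-only
target model). Fine-tuning then trains all parameters with the ordinary
training loop — no freezing, fresh optimizer state. Preprocessing statistics
are never transferred: each experiment fits its own on its development fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from icu_acuity.evaluation import bootstrap_ci, chronological_split
from icu_acuity.models import GRUClassifier, ModelConfig, train

EHR_PARAM_NAMES = ("ehr.W", "ehr.U", "ehr.b")
HEAD_PARAM_NAMES = ("head.w", "head.b")


class TransferError(ValueError):
    pass


@dataclass(frozen=True)
class TransferSpec:
    """What to copy from the source checkpoint and whether to freeze it."""

    transfer_head: bool = False
    freeze_transferred: bool = False


@dataclass
class SourceResult:
    """Pretrained source model with its chronological-holdout evaluation."""

    checkpoint: dict[str, np.ndarray]
    auroc: float
    ci_lower: float
    ci_upper: float
    val_scores: np.ndarray
    val_labels: np.ndarray
    history: object = field(repr=False, default=None)


def pretrain_source(
    source_stays: Sequence,
    model_config: ModelConfig,
    base_seed: int = 0,
    holdout_fraction: float = 0.20,
    n_boot: int = 100,
) -> SourceResult:
    """Train the vitals-only model on the source cohort's chronological 80%.

    Evaluates on the final chronological 20% with a percentile bootstrap and
    returns the checkpoint consumed by :func:`initialize_from_source`.
    """
    from icu_acuity.pipeline import DischargePipeline  # local import: avoid cycle

    dev, val = chronological_split(source_stays, holdout_fraction)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(500,))
    )
    pipe = DischargePipeline(use_activity=False, model_config=model_config)
    pipe.fit(dev, rng)
    scores = pipe.score(val)
    labels = np.array([s.label for s in val])
    boot_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(501,))
    )
    point, lo, hi, _ = bootstrap_ci(scores, labels, n_boot=n_boot, rng=boot_rng)
    return SourceResult(
        checkpoint=pipe.model.clone_params(),
        auroc=point,
        ci_lower=lo,
        ci_upper=hi,
        val_scores=scores,
        val_labels=labels,
        history=pipe.history,
    )


def initialize_from_source(
    target_model: GRUClassifier,
    source_checkpoint: dict[str, np.ndarray],
    spec: TransferSpec = TransferSpec(),
) -> dict:
    """Copy the source model's recurrent weights and biases into the EHR branch.

    Only the ``ehr.*`` GRU parameters are overwritten (plus the head when
    ``transfer_head`` is set and shapes permit); every other parameter keeps
    its current value. Idempotent. Returns an audit record listing exactly
    which parameter groups were overwritten.
    """
    to_copy = list(EHR_PARAM_NAMES)
    if spec.transfer_head:
        to_copy += list(HEAD_PARAM_NAMES)
    for name in to_copy:
        if name not in source_checkpoint:
            raise TransferError(f"source checkpoint lacks parameter '{name}'")
        if name not in target_model.params:
            raise TransferError(f"target model lacks parameter '{name}'")
        if source_checkpoint[name].shape != target_model.params[name].shape:
            raise TransferError(
                f"shape mismatch for '{name}': source "
                f"{source_checkpoint[name].shape} vs target "
                f"{target_model.params[name].shape}"
            )
    for name in to_copy:
        target_model.params[name] = source_checkpoint[name].copy()
    if spec.freeze_transferred:
        target_model.frozen |= set(to_copy)
    audit = {
        "overwritten": sorted(to_copy),
        "untouched": sorted(set(target_model.params) - set(to_copy)),
        "frozen": sorted(target_model.frozen),
    }
    return audit


def write_audit(audit: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(audit, indent=2))


def fine_tune(
    target_model: GRUClassifier,
    target_data: Sequence,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
):
    """Continue training a (possibly transfer-initialized) model as normal."""
    return train(target_model, list(target_data), config, rng=rng)
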