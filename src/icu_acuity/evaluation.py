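"""Evaluation protocols: repeated stratified 5-fold CV and chronological holdout.

The small multi-modal cohort is evaluated with repeated (default 100x)
randomized stratified 5-fold cross-validation: each repetition's value is the
unweighted mean AUROC over its five validation folds, and the 95% interval is
the 2.5th/97.5th percentile of the repetition values. The large source cohort
uses the final chronological 20% of stays as a holdout, with a percentile
bootstrap (default 100 resamples) over its validation predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


class MetricError(ValueError):
    pass


class StratificationError(ValueError):
    pass


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise MetricError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise MetricError("AUROC is undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def stratified_kfold(
    labels: Sequence[int], k: int = 5, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Randomized stratified folds with per-class counts within 1 of proportionality.

    Classes are shuffled and dealt ``len(class) // k`` per fold; each class's
    remainder goes to the folds with the smallest running totals, so overall
    fold sizes also differ by at most one.
    """
    labels = np.asarray(labels)
    rng = rng if rng is not None else np.random.default_rng()
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        cls = classes[counts.argmin()]
        raise StratificationError(
            f"class {cls!r} has {counts.min()} member(s), fewer than k={k}"
        )
    folds: list[list[int]] = [[] for _ in range(k)]
    sizes = np.zeros(k, dtype=int)
    for cls in classes[np.argsort(-counts, kind="stable")]:
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        base, rem = divmod(idx.size, k)
        # remainder goes to currently smallest folds (random tie-break)
        order = rng.permutation(k)
        order = order[np.argsort(sizes[order], kind="stable")]
        extra = np.zeros(k, dtype=int)
        extra[order[:rem]] = 1
        pos = 0
        for f in range(k):
            take = base + extra[f]
            folds[f].extend(idx[pos : pos + take].tolist())
            sizes[f] += take
            pos += take
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def chronological_split(stays: Sequence, holdout_fraction: float = 0.20):
    """Time-ordered split: the latest-admitted ceil(fraction * n) stays validate.

    Ties on admission time break by stay_id.
    """
    order = sorted(range(len(stays)), key=lambda i: (stays[i].admit_time, stays[i].stay_id))
    n_val = int(np.ceil(holdout_fraction * len(stays)))
    dev_idx, val_idx = order[: len(stays) - n_val], order[len(stays) - n_val :]
    return [stays[i] for i in dev_idx], [stays[i] for i in val_idx]


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, np.ndarray]:
    """Percentile bootstrap over (score, label) pairs.

    Single-class resamples are redrawn. Returns (point AUROC, 2.5th, 97.5th
    percentile, bootstrap values).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = rng if rng is not None else np.random.default_rng()
    point = auroc(scores, labels)
    boots = np.empty(n_boot)
    n = scores.size
    for b in range(n_boot):
        for _ in range(10_000):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
        else:  # pragma: no cover - both classes present, so a mixed draw exists
            raise MetricError("could not draw a two-class bootstrap resample")
        boots[b] = auroc(scores[idx], labels[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi), boots


@dataclass
class CVSummary:
    """Repetition-level AUROCs with mean and percentile 95% interval."""

    rep_auroc: np.ndarray
    mean_auroc: float
    ci_lower: float
    ci_upper: float

    @classmethod
    def from_reps(cls, rep_auroc: np.ndarray) -> "CVSummary":
        rep_auroc = np.asarray(rep_auroc, dtype=float)
        lo, hi = np.percentile(rep_auroc, [2.5, 97.5])
        return cls(
            rep_auroc=rep_auroc,
            mean_auroc=float(rep_auroc.mean()),
            ci_lower=float(lo),
            ci_upper=float(hi),
        )

    def to_dict(self) -> dict:
        return {
            "mean_auroc": self.mean_auroc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "rep_auroc": self.rep_auroc.tolist(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def make_fold_assignments(
    labels: Sequence[int], reps: int, k: int, seed: int
) -> list[list[np.ndarray]]:
    """Deterministic per-repetition stratified fold assignments."""
    out = []
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(77, rep))
        )
        out.append(stratified_kfold(labels, k=k, rng=rng))
    return out


def repeated_cv(
    stays: Sequence,
    pipeline_factory: Callable[[], object],
    reps: int = 100,
    k: int = 5,
    base_seed: int = 0,
    fold_assignments: list[list[np.ndarray]] | None = None,
    fit_stream_key: int = 0,
) -> CVSummary:
    """Repeated stratified k-fold CV of a fit/score pipeline.

    ``pipeline_factory()`` must return a fresh object with
    ``fit(dev_stays, rng)`` and ``score(stays) -> array`` so that every
    fold fits its own preprocessing statistics and model on its development
    portion only. ``fold_assignments`` allows callers to pair fold draws
    across experiment arms; ``fit_stream_key`` decorrelates the training
    randomness of paired arms without touching the fold stream.
    """
    labels = np.asarray([s.label for s in stays])
    if fold_assignments is None:
        fold_assignments = make_fold_assignments(labels, reps, k, base_seed)
    if len(fold_assignments) != reps:
        raise ValueError("fold_assignments length must equal reps")
    rep_values = np.empty(reps)
    for rep, folds in enumerate(fold_assignments):
        fold_aurocs = np.empty(k)
        for f, val_idx in enumerate(folds):
            val_mask = np.zeros(len(stays), dtype=bool)
            val_mask[val_idx] = True
            dev = [s for s, m in zip(stays, val_mask) if not m]
            val = [s for s, m in zip(stays, val_mask) if m]
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=base_seed, spawn_key=(fit_stream_key, rep, f)
                )
            )
            try:
                pipe = pipeline_factory()
                pipe.fit(dev, rng)
                scores = np.asarray(pipe.score(val))
                fold_aurocs[f] = auroc(scores, labels[val_idx])
            except (MetricError, StratificationError) as exc:
                raise type(exc)(f"repetition {rep}, fold {f}: {exc}") from exc
        rep_values[rep] = fold_aurocs.mean()
    return CVSummary.from_reps(rep_values)
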