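"""Five-row experiment matrix: source model plus four target-cohort variants.

Rows mirror the study's result table: (1) source cohort, vitals only,
single-cohort training, evaluated on a chronological 20% holdout with a
percentile bootstrap; (2-5) target cohort under {vitals, vitals+activity} x
{single-cohort, transfer} evaluated with repeated stratified 5-fold CV. One
source pretraining run feeds both transfer rows, and within each CV
repetition all four target rows share the same fold assignment so row
differences reflect modality and training scheme rather than fold luck.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from icu_acuity.cohort import CohortConfig, generate_cohort
from icu_acuity.evaluation import CVSummary, make_fold_assignments, repeated_cv
from icu_acuity.models import ModelConfig
from icu_acuity.pipeline import DischargePipeline, prepare_stays
from icu_acuity.transfer import SourceResult, pretrain_source

# (row key, cohort, input data, training scheme, use_activity, use_transfer)
TARGET_ROWS = [
    ("target_ehr_single", "target", "vitals", "single-cohort", False, False),
    ("target_multimodal_single", "target", "vitals+activity", "single-cohort", True, False),
    ("target_ehr_transfer", "target", "vitals", "transfer", False, True),
    ("target_multimodal_transfer", "target", "vitals+activity", "transfer", True, True),
]
SOURCE_ROW = ("source_ehr_single", "source", "vitals", "single-cohort")


class ExperimentConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    source: CohortConfig
    target: CohortConfig
    model: ModelConfig = ModelConfig()
    reps: int = 100
    k: int = 5
    base_seed: int = 0
    n_boot: int = 100
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.target.include_activity:
            raise ExperimentConfigError("target cohort must include activity data")
        if self.source.include_activity:
            raise ExperimentConfigError("source cohort must be vitals-only")
        if self.reps < 1 or self.k < 2:
            raise ExperimentConfigError("reps must be >= 1 and k >= 2")


def desk_model_config(**overrides) -> ModelConfig:
    """Desk-scale training schedule used by the bundled analysis runs."""
    base = dict(max_epochs=20, patience=3)
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class MatrixResult:
    table: pd.DataFrame
    cv_summaries: dict[str, CVSummary]
    source: SourceResult = field(repr=False, default=None)
    config: ExperimentConfig = None
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "rep_auroc": {k: v.rep_auroc.tolist() for k, v in self.cv_summaries.items()},
        }


def run_matrix(config: ExperimentConfig) -> MatrixResult:
    """Run all five experiment rows end-to-end on freshly generated cohorts."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    source_stays = prepare_stays(generate_cohort(config.source))
    target_stays = prepare_stays(generate_cohort(config.target))
    timings["generate_and_prepare"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    source = pretrain_source(
        source_stays, config.model, base_seed=config.base_seed, n_boot=config.n_boot
    )
    timings["pretrain_source"] = time.perf_counter() - t0

    rows = [
        {
            "row": SOURCE_ROW[0],
            "cohort": SOURCE_ROW[1],
            "input_data": SOURCE_ROW[2],
            "training_scheme": SOURCE_ROW[3],
            "auroc": source.auroc,
            "ci_lower": source.ci_lower,
            "ci_upper": source.ci_upper,
        }
    ]

    labels = [s.label for s in target_stays]
    folds = make_fold_assignments(labels, config.reps, config.k, config.base_seed)
    cv_summaries: dict[str, CVSummary] = {}
    for row_idx, (key, cohort, inputs, scheme, use_act, use_transfer) in enumerate(
        TARGET_ROWS
    ):
        t0 = time.perf_counter()
        ckpt = source.checkpoint if use_transfer else None

        def factory(use_act=use_act, ckpt=ckpt):
            return DischargePipeline(
                use_activity=use_act,
                model_config=config.model,
                source_checkpoint=ckpt,
            )

        summary = repeated_cv(
            target_stays,
            factory,
            reps=config.reps,
            k=config.k,
            base_seed=config.base_seed,
            fold_assignments=folds,
            fit_stream_key=row_idx + 1,
        )
        cv_summaries[key] = summary
        timings[key] = time.perf_counter() - t0
        rows.append(
            {
                "row": key,
                "cohort": cohort,
                "input_data": inputs,
                "training_scheme": scheme,
                "auroc": summary.mean_auroc,
                "ci_lower": summary.ci_lower,
                "ci_upper": summary.ci_upper,
            }
        )

    table = pd.DataFrame(rows)
    result = MatrixResult(
        table=table, cv_summaries=cv_summaries, source=source, config=config,
        timings=timings,
    )
    if config.outdir is not None:
        save_result(result, config.outdir)
    return result


REQUIRED_COLUMNS = ["cohort", "input_data", "training_scheme", "auroc", "ci_lower", "ci_upper"]


def report(table: pd.DataFrame) -> str:
    """Render the five-row results table as aligned text (AUROC with 95% CI)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table is missing columns: {missing}")
    lines = [
        f"{'Cohort':<8} {'Input data':<17} {'Training scheme':<16} AUROC (95% CI)"
    ]
    for r in table.itertuples(index=False):
        lines.append(
            f"{r.cohort:<8} {r.input_data:<17} {r.training_scheme:<16} "
            f"{r.auroc:.3f} ({r.ci_lower:.3f}-{r.ci_upper:.3f})"
        )
    return "\n".join(lines)


def save_result(result: MatrixResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(outdir / "matrix_results.csv", index=False)
    (outdir / "matrix_results.json").write_text(json.dumps(result.to_dict(), indent=2))
    (outdir / "matrix_report.txt").write_text(report(result.table) + "\n")
    (outdir / "timings.json").write_text(json.dumps(result.timings, indent=2))


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file with source/target/model/run keys."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    source = CohortConfig(**{"include_activity": False, **raw.get("source", {})})
    target = CohortConfig(**{"include_activity": True, **raw.get("target", {})})
    model = ModelConfig(**raw.get("model", {}))
    run = raw.get("run", {})
    return ExperimentConfig(
        source=source,
        target=target,
        model=model,
        reps=int(run.get("reps", 100)),
        k=int(run.get("k", 5)),
        base_seed=int(run.get("base_seed", 0)),
        n_boot=int(run.get("n_boot", 100)),
        outdir=run.get("outdir"),
    )
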