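"""Run the five-row experiment matrix end-to-end and save all results.

Rows: source model (chronological holdout + bootstrap CI) and the four
target-cohort variants ({vitals, vitals+activity} x {single-cohort,
transfer}) under repeated stratified 5-fold cross-validation with paired
fold assignments. Writes the results table, per-repetition AUROCs, and a
rendered report under results/matrix/.
"""

import sys

from icu_acuity.cohort import source_cohort_config, target_cohort_config
from icu_acuity.experiments import (
    ExperimentConfig,
    desk_model_config,
    report,
    run_matrix,
)


def main(seed=0, reps=10):
    cfg = ExperimentConfig(
        source=source_cohort_config(n_stays=2000, seed=seed),
        target=target_cohort_config(n_stays=51, seed=seed + 1),
        model=desk_model_config(),
        reps=reps,
        base_seed=seed,
        outdir="results/matrix",
    )
    result = run_matrix(cfg)
    print(report(result.table))
    means = result.table.set_index("row")["auroc"]
    print(
        f"\ntransfer gain (vitals only):     "
        f"{means['target_ehr_transfer'] - means['target_ehr_single']:+.3f} AUROC"
    )
    print(
        f"transfer gain (vitals+activity): "
        f"{means['target_multimodal_transfer'] - means['target_multimodal_single']:+.3f} AUROC"
    )
    print("results written to results/matrix/")


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    reps = int(sys.argv[2]) if len(sys.argv) > 2 else 10
    main(seed, reps)
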