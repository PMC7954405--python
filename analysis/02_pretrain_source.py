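"""Pretrain the vitals-only GRU on the source cohort and evaluate it.

Trains on the chronological first 80% of the source cohort (with its internal
20% early-stopping carve-out), scores the final chronological 20%, reports
AUROC with a 100-resample percentile bootstrap, and saves the checkpoint that
the transfer-learning rows of the experiment matrix reuse.
"""

import json
import sys
from pathlib import Path

from icu_acuity.cohort import generate_cohort, source_cohort_config
from icu_acuity.experiments import desk_model_config
from icu_acuity.models import save_checkpoint
from icu_acuity.pipeline import prepare_stays
from icu_acuity.transfer import pretrain_source

OUT = Path("results/source_model")


def main(seed=0):
    stays = prepare_stays(generate_cohort(source_cohort_config(n_stays=2000, seed=seed)))
    result = pretrain_source(stays, desk_model_config(), base_seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    save_checkpoint(result.checkpoint, OUT / "source_checkpoint.npz")
    eval_info = {
        "auroc": round(result.auroc, 4),
        "ci_lower": round(result.ci_lower, 4),
        "ci_upper": round(result.ci_upper, 4),
        "n_validation": int(result.val_labels.size),
    }
    (OUT / "source_eval.json").write_text(json.dumps(eval_info, indent=2))
    result.history.to_csv(OUT / "training_history.csv", index=False)
    print(
        f"source model: chronological-holdout AUROC {result.auroc:.3f} "
        f"(95% CI {result.ci_lower:.3f}-{result.ci_upper:.3f}, "
        f"n_val={result.val_labels.size})"
    )
    print(f"checkpoint and evaluation written to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
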