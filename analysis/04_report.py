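"""Summarize a saved experiment-matrix run.

Renders the five-row table, the per-repetition spread of each cross-validated
row, and the paired per-repetition transfer comparisons from
results/matrix/matrix_results.{csv,json}.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from icu_acuity.experiments import report

IN = Path("results/matrix")


def main():
    table = pd.read_csv(IN / "matrix_results.csv")
    reps = json.loads((IN / "matrix_results.json").read_text())["rep_auroc"]
    print(report(table))
    print("\nPer-repetition spread (cross-validated rows):")
    for key, vals in reps.items():
        v = np.asarray(vals)
        print(f"  {key:<28} mean {v.mean():.3f}  min {v.min():.3f}  max {v.max():.3f}")
    pairs = [
        ("target_ehr_transfer", "target_ehr_single", "vitals only"),
        ("target_multimodal_transfer", "target_multimodal_single", "vitals+activity"),
    ]
    print("\nPaired transfer comparisons (shared fold assignments):")
    for a, b, label in pairs:
        wins = np.mean(np.asarray(reps[a]) > np.asarray(reps[b]))
        print(f"  transfer beats single-cohort ({label}) in {100 * wins:.0f}% of repetitions")


if __name__ == "__main__":
    main()
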