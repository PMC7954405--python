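"""Generate the two synthetic study cohorts and summarize their structure.

Writes long-format vitals/activity/label tables for a large vitals-only
source cohort and a small multi-modal target cohort under results/cohorts/,
and prints the summary statistics a cohort table would report: label split,
stay lengths, vital-sign medians, and daily actigraphy feature medians.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from icu_acuity.activity import ACTIVITY_FEATURE_NAMES, activity_feature_matrix
from icu_acuity.cohort import (
    cohort_tables,
    generate_cohort,
    source_cohort_config,
    target_cohort_config,
    write_cohort,
)

OUT = Path("results/cohorts")


def summarize(name, stays):
    labels = np.array([s.label for s in stays])
    los = np.array([s.los_hours for s in stays])
    print(f"\n== {name} cohort: n={len(stays)} ==")
    print(f"unsuccessful discharge: {labels.sum()} ({100 * labels.mean():.1f}%)")
    print(f"ICU length of stay (h): median {np.median(los):.0f} "
          f"(IQR {np.percentile(los, 25):.0f}-{np.percentile(los, 75):.0f})")
    vit = pd.concat([s.vitals for s in stays])
    med = vit.groupby("variable")["value"].median()
    print("vital-sign medians:", ", ".join(f"{k}={v:.1f}" for k, v in med.items()))
    if stays[0].activity is not None:
        feats = np.vstack(
            [activity_feature_matrix(s.activity, s.admit_time).values for s in stays]
        )
        med = np.nanmedian(feats, axis=0)
        print("daily actigraphy medians:",
              ", ".join(f"{n}={v:.2f}" for n, v in zip(ACTIVITY_FEATURE_NAMES, med)))


def main(seed=0):
    source = generate_cohort(source_cohort_config(n_stays=2000, seed=seed))
    target = generate_cohort(target_cohort_config(n_stays=51, seed=seed + 1))
    summarize("source (vitals-only)", source)
    summarize("target (multi-modal)", target)
    write_cohort(source, OUT / "source")
    write_cohort(target, OUT / "target")
    n_rows = sum(len(t) for t in cohort_tables(target).values())
    print(f"\nwrote cohort tables under {OUT}/ (target tables: {n_rows} rows)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
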