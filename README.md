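# icu-acuity

Multi-modal patient-acuity analysis for the intensive care unit: recurrent
models over routinely charted vital signs and wrist-actigraphy features
predict whether a patient will ultimately be discharged from hospital
successfully (home or rehabilitation) or unsuccessfully (in-hospital death,
hospice, or transfer), and a partial-weight transfer-learning protocol
carries representations learned on a large vitals-only cohort into a small
multi-modal cohort. Because the corresponding clinical data are access
restricted, the package ships a synthetic-cohort generator with the same
statistical structure — irregular six-channel vitals, zero-inflated
minute-epoch activity counts, and a discharge label driven by a latent
severity process — so the whole analysis runs end to end on any machine.

It is written for researchers in clinical machine learning who want a
tested, reproducible reference implementation of this style of analysis:
hourly resampling and development-set-only preprocessing, variable-length
GRU classifiers, fine-tuning from a pretrained source model, and repeated
stratified cross-validation with percentile confidence intervals.

## The model

Each ICU stay contributes a variable-length matrix **X** ∈ ℝ^(T×6) of hourly
vitals (diastolic/systolic BP, heart rate, respiratory rate, SpO2,
temperature) and, in the multi-modal cohort, a matrix **A** ∈ ℝ^(D×9) of
daily actigraphy statistics (min, max, mean, variance, SD, immobile
fraction, IQR, RMSSD, SD of hourly RMSSD). A single-layer GRU

  z_t = σ(W_z x_t + U_z h_{t−1} + b_z),  r_t = σ(W_r x_t + U_r h_{t−1} + b_r),
  n_t = tanh(W_n x_t + r_t ⊙ U_n h_{t−1} + b_n),  h_t = (1−z_t) ⊙ n_t + z_t ⊙ h_{t−1}

with 128 hidden units summarizes each stream; the vitals-only model feeds
h_T to a sigmoid linear head, while the parallel model concatenates the two
final hidden states (256) before the head. Risk scores are also exposed at
every 24-h boundary. Training uses binary cross-entropy on the final
prediction, Adam (lr 10⁻³, L2 weight decay 10⁻³), batches of 32, 25%
dropout, and early stopping on a random 20% development carve-out. Transfer
learning copies the source model's GRU weights and biases into the EHR
branch only; activity branch and head stay randomly initialized, and all
parameters are then fine-tuned. Small-cohort rows are evaluated with
repeated stratified 5-fold cross-validation (mean fold AUROC per repetition;
95% CI from the 2.5th/97.5th percentiles across repetitions); the source row
uses the final chronological 20% of stays with a 100-resample bootstrap.

## Worked example

The numbered scripts under `analysis/` run the study end to end:

```bash
python analysis/01_generate_cohorts.py    # synthetic cohorts + summary table
python analysis/02_pretrain_source.py     # vitals-only source model
python analysis/03_run_matrix.py 0 10     # five-row matrix, seed 0, 10 reps
python analysis/04_report.py              # rendered summary
```

A 10-repetition run at the default desk scale (source n = 2,000, target
n = 51, `python analysis/03_run_matrix.py 0 10`) prints:

```
Cohort   Input data        Training scheme  AUROC (95% CI)
source   vitals            single-cohort    0.842 (0.797-0.890)
target   vitals            single-cohort    0.731 (0.678-0.784)
target   vitals+activity   single-cohort    0.743 (0.719-0.780)
target   vitals            transfer         0.718 (0.562-0.775)
target   vitals+activity   transfer         0.752 (0.689-0.781)

transfer gain (vitals only):     -0.013 AUROC
transfer gain (vitals+activity): +0.009 AUROC
```

Read: the large vitals-only cohort supports accurate training (row 1); the
same architecture trained from scratch on 51 stays is clearly worse (rows
2-3); adding the activity modality helps, and transfer combined with the
activity modality ranks first among the four target-cohort rows. The
vitals-only transfer row illustrates the instability this design exhibits
at n = 51 — its interval is by far the widest (one repetition's fine-tuning
collapsed to 0.52), so at a given seed its mean can land below the
single-cohort row even when it wins most paired repetitions at other seeds.
Averaging more repetitions sharpens the picture; per-repetition AUROCs and
paired transfer comparisons are written under `results/matrix/`.

The same flows are available as a CLI (`icu-acuity generate | pretrain |
run-matrix | report`) driven by YAML configs.

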