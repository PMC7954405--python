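# Methods

This note documents the generative model behind the synthetic cohorts, the
preprocessing and modelling conventions, the evaluation protocols, and the
numerical and scale choices the package makes where a convention had to be
fixed.

## Study design

The analysis asks two questions about ICU acuity assessment: (1) does
augmenting routinely charted vital signs with wrist-actigraphy features
improve prediction of eventual hospital-discharge disposition, and (2) can
transfer learning from a large vitals-only cohort rescue model quality in a
small multi-modal cohort? Five experiment rows answer them: a source-cohort
vitals model evaluated on a chronological holdout, and four target-cohort
variants — {vitals, vitals+activity} × {single-cohort, transfer} — evaluated
with repeated stratified 5-fold cross-validation. Within a repetition all
four target rows share one fold assignment, so paired differences reflect
modality and training scheme rather than fold luck (a variance-reduction
addition documented here because it changes what the per-repetition
comparisons mean).

## Synthetic cohort generator

The real cohorts are access restricted, so all inputs are synthetic. The
generator is not a model of any published dataset; it is an artifact whose
distributions are chosen to (a) reproduce the qualitative structure the
pipeline must handle and (b) sit at realistic magnitudes for ICU
populations.

**Latent severity.** Each stay carries an hourly severity path
s_{t+1} = s_t + θ(μ_i − s_t) + v·ε_t (discrete Ornstein–Uhlenbeck), with a
patient-level long-run severity μ_i ~ N(0,1), mean-reversion θ = 0.1 and
volatility v = 0.3. Deviations from μ_i are AR(1) with lag-1 coefficient
1 − θ, which the tests verify by simulation.

**Discharge label.** y_i ~ Bernoulli(σ(a + β·m_i)) where m_i is the mean of
the final 24 h of severity and β = 2. The intercept a is calibrated by root
finding on the cohort's realized m_i so empirical prevalence matches the
configured value (0.35 for the target cohort, 0.25 for the source cohort,
mirroring the class balance such cohorts show).

**Vitals.** Six channels at baselines (DBP 62, SBP 122, HR 88, RR 18.5,
SpO2 97, Temp 37.0 — units mmHg, bpm, breaths/min, %, °C) shifted by a
per-channel severity coefficient (sign: sicker → tachycardic, tachypneic,
febrile, hypotensive, desaturated) times the `vitals_effect` dial. Severity
acts through a mildly convex response (slope increases ~0.5 SD above the
mean — decompensation accelerates), each patient has a baseline offset per
vital (SDs 6/10/7/2/1/0.25 in native units), and each record adds Gaussian
noise. Per hour and channel, 1–3 records appear at random minute offsets
with probability 1 − `missing_rate` (default 0.15). The patient offsets
matter: without them the cohort-mean of a single vital is an almost
noiseless severity readout and even 41 training stays saturate the
achievable AUROC, which is not how real cohorts behave. With them, severity
must be recovered from the joint shift of all six channels — easy at
n ≈ 2,000, unreliable at n = 51, which is precisely the regime the transfer
experiment studies.

**Activity.** One count per minute epoch. A minute is immobile (count 0)
with probability σ(logit(0.6) + b_i + `activity_effect`·s_t); active minutes
draw 1 + NegBin(mean ≈ 6 declining in severity and in the patient mobility
offset b_i ~ N(0, 0.6²), dispersion 1.2). Zero counts coincide exactly with
immobile minutes, so the zero fraction is the mean immobility probability
(checked by Monte Carlo). Daily feature magnitudes land near observed
wrist-actigraphy summaries (mean count ~3, max ~60, immobile fraction ~0.6,
RMSSD ~7 with between-hour SD an order of magnitude smaller). Raw 100 Hz
accelerometry is deliberately not simulated: the features need only epoch
counts, and device count algorithms are proprietary.

**Scale.** Stay lengths are lognormal, floored at 24 h (so at least one
activity window exists): target median 72 h, source median 48 h, capped at
30 days. Admissions spread uniformly over two years so a chronological split
is meaningful. These desk-scale lengths — chosen so that the full
repeated-CV matrix runs on a laptop core — are shorter than the multi-week
stays of specialized ICUs; nothing in the pipeline depends on them, and they
are plain config fields (`los_log_mean`, `los_log_sd`).

**What passing tests do and do not show.** The generator has no circadian
structure, no treatment feedback, no informative missingness, no correlated
record noise, and its severity link is the same family the label uses.
Green results demonstrate that the pipeline is implemented correctly and
that the transfer/multimodal ordering emerges under a controlled signal;
they say nothing about effect sizes on real ICU data.

## Preprocessing

Vitals are binned to a fixed 1-h grid anchored at admission (half-open bins
[h, h+1); a boundary record belongs to the later bin), averaging multiple
records per bin; empty bins are explicitly masked. Activity counts are
windowed into consecutive 24-h intervals from admission; a trailing partial
window is kept if it has ≥ 2 epochs. Nine statistics per window use
sample (ddof = 1) variance/SD and linearly interpolated percentiles;
"immobile" is implemented as the fraction of epochs at or below a threshold
(default 0), and "SD of RMSSD" as the ddof-1 SD of per-hour (60-epoch)
RMSSD values — both definitions are configurable because the field uses the
terms loosely, and the chosen readings are the ones consistent with
bounded-[0,1] and an-order-below-RMSSD magnitudes respectively.

Per-feature statistics are fitted on development data only: caps at the
1st/99th percentile (linear interpolation), imputation median, and
standardization mean/SD computed on the capped pool (ddof = 0; a constant
feature gets SD 1 to avoid division by zero on tiny folds). Application
order is cap → forward-fill (leading gaps take the dev median) →
z-score; consequently the originally observed cells of the development pool
standardize to exactly zero mean and unit SD, while imputed cells inherit
capped predecessors. Every cross-validation fold and the chronological split
fit their own statistics; nothing is ever fitted on held-out stays, and the
early-stopping carve-out is drawn inside the development portion. Whether
the carve-out should also be excluded from the preprocessing fit is
genuinely open; the package fits on the full development fold.

## Models and training

Single-layer GRUs (gate order update/reset/candidate, candidate with
reset-gated hidden term, h_t = (1−z)⊙n + z⊙h_{t−1}), hidden size 128 in
every branch; the parallel model runs independent GRUs over hourly vitals
and daily activity features and concatenates final states (256) before a
sigmoid linear head. Loss is binary cross-entropy on the final prediction
only; per-window scores (head applied at each 24-h boundary) are exposed for
monitoring, with optional window supervision behind a config flag (off by
default). Adam with lr 10⁻³ and coupled L2 weight decay 10⁻³, batch size 32,
25% inverted dropout on branch inputs and on the pre-head representation
(training only), gradient clipping at global norm 5 (a numerical safeguard;
it rarely binds at these scales). Early stopping monitors the loss of a
random 20% carve-out with patience, restoring the best parameters.
Variable-length sequences are handled by packed computation — each
sequence's final state is read at its own last step, never at padding — and
the per-window trajectory is prefix-consistent by construction: truncating a
stay at a 24-h boundary reproduces that window's score bit for bit.

The recurrent kernels are NumPy/numba with hand-derived backpropagation
through time, verified against central finite differences in float64.
Training runs in float32; with fixed seeds a train/predict cycle is bitwise
reproducible on one CPU.

Library defaults are max_epochs = 100, patience = 10. The bundled analysis
scripts and acceptance runs use a desk-scale schedule (max_epochs = 20,
patience = 3): at these cohort sizes early stopping terminates training well
before either cap, and pilot runs at 40/5 and 30/4 gave indistinguishable
results.

## Transfer learning

The source model trains on the chronological first 80% of the vitals-only
cohort. Its GRU parameters (`ehr.W`, `ehr.U`, `ehr.b` — weights *and*
biases) are copied bitwise into the target model's EHR branch; the activity
branch and prediction head keep their random initialization. Head transfer
is available behind a flag but is only shape-legal for the vitals-only
target model (128- vs 256-dimensional head input). Fine-tuning then trains
all parameters with a fresh optimizer; no freezing or discriminative
learning rates. Preprocessing statistics are never transferred — each
experiment fits its own. The copy is idempotent, audited (the overwritten
parameter set is recorded), and validated bitwise in the tests.

## Evaluation

AUROC is the Mann–Whitney probability that a positive outranks a negative,
ties counted ½. Stratified 5-fold assignment shuffles within class, deals
`count // k` per fold, and sends each class's remainder to the currently
smallest folds, so per-class counts are within one of proportionality *and*
overall fold sizes differ by at most one (for a 33/18 cohort: fold sizes
{11,10,10,10,10} with 3–4 minority cases each). Repetition values are
unweighted means of the five fold AUROCs; the 95% interval is the
2.5th/97.5th percentile (linear interpolation) of the repetition values — no
normal approximation. The source row uses the latest-admitted ⌈0.2 n⌉ stays
(ties broken by stay id) and a percentile bootstrap over validation
predictions in which single-class resamples are redrawn. Published analyses
of this design use 100 repetitions; the bundled runs default to 10–20
repetitions to keep a full matrix in the minutes range, with `reps` a plain
config field.

## Known limitations

Severity-to-observable links share the logistic/linear family with the
generator's label link, so absolute AUROCs are optimistic relative to real
data. Cohort realizations at n = 51 vary widely in difficulty — some
realizations are separable enough that from-scratch training matches
transfer, mirroring the wide repetition-level spread such small cohorts
show. The parallel model requires both modalities for every stay; stays
missing an activity series are a contract error, not an imputation case.
Probability calibration, attention mechanisms, multi-layer recurrences, and
hyperparameter search are out of scope.
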