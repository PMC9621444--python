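# Methods

This note documents the models, the synthetic data, and the design decisions
behind `hhc-cdss`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

The prediction target is a binary, episode-level outcome: whether a hospital
admission ends in a clinician decision to start holistic health care (HHC).
The event is rare (prevalence ≈ 0.43% of admissions) and the useful signal is
temporal — a deterioration in routinely recorded vitals and assessments over
roughly the week before the decision. Three systems are compared on identical
held-out episodes: an LSTM over 8-day feature windows, a simple RNN baseline,
and the deployed four-rule expert system.

## Daily scoring

Scores are computed per patient-day, strictly after preprocessing.

- **Coma Status** is the sum of the eye (1–4), vocal (1–5) and motion (1–6)
  consciousness sub-scales. The attainable range is therefore [3, 15] and the
  implementation enforces it, although the source description nominally
  states a lower bound of 1 (the sub-scale minima make 3 the true floor).
- **Early Warning Score (EWS)** sums seven bin scores. The published bin
  table sums to a maximum of 20 (respiration 3 + SpO2 3 + oxygen 2 +
  temperature 3 + blood pressure 3 + pulse 3 + coma 3), so 20 is the enforced
  ceiling even though the feature description elsewhere says "0–21".
  Continuous bins are closed at the recording precision: the integer
  parameters (respiratory rate, SpO2, systolic BP, heart rate, Coma Status)
  are binned on the nearest integer with gap-free closure (≤8, 9–11, 12–20,
  21–24, ≥25 for respiration, and so on); temperature is binned on tenths of
  a degree (≤35.0 → 3, 35.1–36.0 → 1, 36.1–38.0 → 0, 38.1–39.0 → 1,
  ≥39.1 → 2).
- **TeamEval** `= Pain·5 + BSRS·5 + Nutrition·30` with Pain, BSRS ∈ [0, 10]
  and Nutrition ∈ [0, 6]. (One published table shows these indices starting
  at 1; the wider 0-based domain is admitted, and the text's ranges govern.)
- **HealthScore** combines the three wellness aspects with disease-specific
  weights: `TeamEval·W_TeamEval + min(B,20)·5·W_CCI + min(C,20)·5·W_EWS`,
  where B is the Charlson Comorbidity Index (consumed as a precomputed
  integer; deriving it from diagnosis codes is out of scope) and C the EWS.
  The CCI and EWS terms are read as capped index values times their ratio
  (5), parallel to the TeamEval construction — this makes the rule
  thresholds 40/50/70 attainable and meaningful. The weight triples are
  CVA (0.37, 0.34, 0.29), Dementia (0.7, 0.19, 0.10), Cancer
  (0.61, 0.19, 0.20), Others (0.10, 0.80, 0.10); the Dementia row sums to
  0.99 as published, and no sum-to-one constraint is imposed.

## Preprocessing

A single fixed pass per cohort: (1) assessment/comorbidity fields (pain,
BSRS, nutrition, CCI) default to 0 when empty, an empty oxygen flag becomes
False; (2) missing physiological vitals and coma sub-scales are filled by
linear interpolation within each stay, with nearest-value extension at the
stay edges and a cohort-mean fallback for an all-missing series (linear
interpolation is undefined in those cases; the choice is ours); (3) a value
deviating from the cohort field mean by more than two population standard
deviations is blanked and re-interpolated. The outlier rule is read
two-sided (|x − mean| > 2σ): a one-sided reading would never flag
hypothermia or bradycardia. Field statistics are computed cohort-wide, once,
before replacement — per-patient statistics are unstable for short stays,
and no fixpoint iteration is performed. Zero-filling never touches
physiological vitals (a temperature of 0 is a corruption, not a
measurement). Interpolated coma sub-scales are rounded back onto their
integer scales. The two-SD rule is applied to the five continuous vitals
only; applying it to the near-ceiling coma sub-scales would flag genuine
low-consciousness readings.

## Feature encoding and windows

Each patient-day vector has a continuous block (age, HealthScore,
temperature, heart rate, respiratory rate, SpO2, systolic BP) min–max scaled
with parameters fitted on the training split only and frozen (out-of-range
values at prediction time are clipped), a discrete block (hospitalization
days `D_delta = DD − ED` floored at 1 and computed with the running date
while in stay; EWS; Coma Status; oxygen flag), and a one-hot disease block.
Coma Status appears both inside the EWS and as a standalone feature, as the
feature list prescribes. Patient identifiers and admission timestamps are
keys and window anchors, never model inputs — an identifier as a learned
feature cannot generalize.

A window is 8 consecutive in-stay days; one window per day with at least 7
predecessors. A window is labelled positive when the episode has an HHC date
at most 14 days after the window's end; windows extending past the HHC date
are not emitted. The 14-day labelling horizon operationalizes the two-week
evaluation validity rule for training.

## Sequence models

The LSTM (and tanh-RNN baseline) is implemented directly in numpy: Glorot
initialization, forget-gate bias 1, a single sigmoid output unit on the last
hidden state, binary cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
and exact backpropagation through time (verified against numerical gradients
in the test suite). Defaults: one recurrent layer of 32 units within an
input/recurrent/output three-layer stack (a three-recurrent-layer reading is
reachable via `n_recurrent_layers`), 30 epochs, learning rate 1e-3, batch
size 64, decision threshold 0.5. Inputs are additionally normalized to
[0, 1] using training-set ranges stored with the model, so prediction-time
scaling is frozen. Training is deterministic given (data, config, seed) on a
single thread, and models serialize to a self-describing `.npz` that reloads
with bit-identical predictions.

Class imbalance is handled per the study protocol: all positive windows are
kept and negative windows are undersampled to a 1:4 ratio at the episode
level (whole episodes in shuffled order, the last truncated to hit the exact
count) — episode-level sampling avoids splitting near-duplicate windows
across the class balance. A class-weighted loss is available as a config
flag but off by default, the 1:4 resample being the primary mechanism. When
a hyperparameter grid is supplied, candidates are scored by mean fold
sensitivity under stratified 10-fold cross-validation.

## Rule engine and cohort filters

The four rules fire on a day's scores; an episode is flagged when any
in-stay day fires, and the earliest firing day is the forecast date. The
rehabilitation exclusion applies to rule 3 only (it is stated inside that
rule). "Nutrient" and "Nutrition" are the same index.

The evaluation cohort drops, in attribution order: psychiatric in-patients,
demo cases, stays shorter than 7 days, and episodes whose HHC decision came
within 7 days of admission. The third criterion is printed in the source as
excluding patients hospitalized *at least* 7 days, but its stated rationale
(too little history) implies the opposite; the filter excludes short stays.
This reading is deliberate and worth flagging prominently.

## Evaluation

Episode-level confusion matrices under the validity rule: an HHC episode is
a true positive only when flagged with |forecast − HHC date| ≤ 14 days (the
two-week window is read symmetrically; no direction is stated). Metrics with
zero denominators are reported as undefined, never as 0. ROC-AUC uses the
rank-sum/trapezoidal construction with midranks for ties; an independent
O(n²) pairwise-concordance oracle guards it in the tests.

The published performance table is reproduced from the published confusion
matrices at printed precision, with three documented exceptions: the printed
LSTM accuracy (99.65%) and LSTM specificity (99.95%) are inconsistent with
the LSTM matrix itself (which yields 99.70% and 99.78%), and the printed RNN
sensitivity (77.33%) likewise (matrix: 77.01%). The implementation is
matrix-faithful.

## Synthetic cohort

The generator emulates the published dataset characteristics: truncated
normal marginals for every vital, assessment and demographic field (e.g. age
53.79 ± 24.14 on 0–107, pulse 81.63 ± 15.79 on 0–133), stay length
7.89 ± 11.59 days truncated to [1, 60], HHC prevalence 0.0043, configurable
missingness (2% of vital cells) and outlier corruption (0.5%, excursions of
2.5–4 population SDs). Repeated-measure fields decompose into a stable
patient-level baseline plus day-to-day noise with the published marginal SD
preserved (within-day SD share 0.7 for vitals, 0.3 for assessment indices
and coma scales). The HHC onset is placed at least 7 days after admission so
generated positives survive the cohort filters. Deterioration is a per-day
additive drift over the 7 days before the HHC date (respiration +1.2/day,
SpO2 −0.7, systolic BP −4.0, pulse +5.0, temperature +0.22 °C, coma scales
−0.25/−0.35/−0.40, and mild drift on pain/BSRS/nutrition of
+0.10/+0.10/+0.05): the deterioration that precedes an HHC decision is
predominantly physiological, which is also why threshold rules on the
care-team indices miss most cases. HHC patients additionally carry +2 CCI.
Disease mix (CVA 0.05, Dementia 0.05, Cancer 0.20, Others 0.70), the flag
rates (psychiatric 2%, demo 0.5%, rehabilitation 3%) and the oxygen
prescription rates (5% baseline, rising to 45% at peak deterioration) are
stated config with no published counterpart.

What the generator does **not** emulate: inter-vital physiological
correlation beyond the shared drift, disease-specific trajectories, skewed
(non-Gaussian) index distributions, or any joint structure between
comorbidity and vitals. Consequently, passing end-to-end tests demonstrates
that the pipeline learns and evaluates a week-scale deterioration signal
correctly — not that the published operating points transfer to real data.
Two visible artefacts of marginal-only calibration: the published marginals
give a typical Dementia HealthScore near the rule-3 threshold of 40, so the
rule engine persistently flags many non-HHC dementia patients (low rule
precision), and at 0.43% prevalence with a 0.5 threshold per-window false
positives accumulate over a stay, so model specificity on the synthetic
cohort sits far below the published 99%+ even while ranking (AUC) is strong.

## Problem sizes and reproducibility

The package's study size is 20,000 patients (~160,000 patient-days, ~43
training HHC episodes), which the full pipeline processes — including
training both recurrent models — in well under a minute on one CPU; the test
suite uses smaller cohorts (250–50,000 patients) per property. One root seed
drives every stochastic stage through named, CRC-derived sub-streams
(`pipeline.sub_seed`), so stages are individually reproducible and two runs
of the same config produce byte-identical metrics JSON.

## Known limitations

- The numpy recurrent networks are CPU-only and unbatched across sequences
  longer than the fixed 8-step window; they are sized for this study, not
  for large-scale reuse.
- The rule engine and scoring constants are config, but no rule learning or
  weight validation is attempted.
- Calibration of predicted probabilities is not assessed (no decision-curve
  or calibration analysis); the default 0.5 threshold is a convention, and
  on rare-event cohorts a threshold chosen on validation data would trade
  the observed specificity/precision balance differently.
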