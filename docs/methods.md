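# Methods

## The problem

IgA nephropathy (IgAN) patients at a single TCM hospital are assigned
up to five concurrent diagnostic subtypes — Qi-Yin Deficiency,
Wind-dampness, Liver-wind, Blood Stasis and Ni-du — from routine
clinical data: age and sex, five laboratory indices (systolic and
diastolic blood pressure, urinary protein content, a five-level
dysmorphic-red-blood-cell grade, eGFR) and 26 binary symptom
indicators.  Because subtypes co-occur, the task is multi-label: five
independent 0/1 decisions per patient, with one subtype (Ni-du, the
severe stage) markedly rarer than the rest.

## Model

Each patient is encoded as a vector x ∈ [0,1]^d (d = 38 for the
default schema: 5 scaled continuous columns, 7 one-hot columns for sex
and DRBC grade, 26 binary symptom columns).  The clinical source data
are tabular, not sequential, so turning them into an LSTM input
requires a tokenization step: column j carries a learned embedding
E_j ∈ R^32 and contributes the token x_j·E_j, giving a length-d
sequence in fixed schema order.  This construction keeps the recurrent
layer's parameter count at exactly 4·((32+32)·32+32) = 8,320 for the
published 32/32 configuration, and gives the attention stage a
meaningful sequence to re-weight.  An absent symptom contributes a zero
token; a present one contributes its embedding; scaled continuous
values interpolate.

The sequence is consumed by a single-layer LSTM with the standard gate
equations (logistic gates, tanh candidate, elementwise products).  The
output gate is the standard σ(W_o x_t + U_o h_{t−1} + b_o).  The
hidden-state sequence passes through inverted dropout (train-time
rescaling by 1/(1−P), identity at inference), then multi-head
self-attention: per head, full-width 32×32 query/key/value projections,
scaled dot-product attention with d_k = 32, heads concatenated and
projected by W_O ∈ R^{128×32}.  Full-width heads (rather than 32/H
splits) keep each head's projection literal at the cost of extra
parameters.  The attended sequence is mean-aggregated over the token
axis (sum and last-token aggregation are selectable), passed through a
32-unit ReLU layer, and a linear layer emits five logits; per-subtype
probabilities are their element-wise logistic.

Training minimizes a class-imbalance-weighted binary cross-entropy
computed directly from logits,

    w_i  = N_neg,i / N_pos,i          (per label, training split only)
    Loss = −mean[ w_i·y·log σ(ẑ) + (1−y)·log(1−σ(ẑ)) ]

with the weight on the positive term only, averaged over all
(sample, label) cells, in the stable softplus formulation (finite for
|logit| ≫ 100).  Optimization is mini-batch Adam (β1 0.9, β2 0.999,
ε 1e-8) with per-epoch reshuffling.

The whole network and its backward pass are implemented on a small
numpy reverse-mode autodiff core written for this package
(`malnet._autodiff`); every operation's gradient and the end-to-end
gradient of the loss are verified against central finite differences in
the test-suite.

## Hyperparameters

| setting       | default | notes                                       |
|---------------|---------|---------------------------------------------|
| token_dim     | 32      | embedding width per encoded column          |
| hidden_dim    | 32      | published hidden-layer width                |
| n_heads       | 4       | published attention-head count              |
| dropout_p     | 0.4     | the published sweep optimum; 0.2 (the other published setting) selectable |
| fc_dim        | 32      | ReLU layer width                            |
| threshold     | 0.5     | strict: label positive iff p > threshold    |
| learning_rate | 1e-4    | published sweep optimum; 1e-3 selectable    |
| epochs        | 500     | fixed-length training, no early stopping    |
| batch_size    | 64      | published sweep optimum                     |

The source study reports two optimization settings (an initial
lr 0.001 / dropout 0.2 configuration and swept optima of lr 0.0001 /
dropout 0.4); both are exposed, the sweep optima are the defaults.
Adam moment constants are not reported and take their standard values.
Parameter initialization (not reported) is uniform ±1/√fan_in per
weight array with zero biases, except the forget-gate bias at 1.0
(standard LSTM practice) and embeddings treated as having fan-in 1.

## Preprocessing protocol

Patients missing more than 20% of their feature values are excluded.
Remaining gaps are imputed (mean for continuous, mode for
binary/categorical); continuous features are min-max scaled to [0,1];
categorical features are one-hot encoded; binary features stay as a
single 0/1 column (two one-hot columns would be redundant).  All
imputation and scaling statistics come from the training partition
only — the study does not state this, and it is adopted to exclude
leakage; test-set values falling outside the training range after
scaling are clipped to [0,1] so the network's documented input domain
holds.  A feature constant in training (scale undefined) transforms to
0.0 with a warning.

The 80/20 split and the five-fold cross-validation use greedy
multi-label stratification, assigning the rarest label's positives
first, so each subtype's prevalence in every partition stays within a
few percentage points of its overall prevalence (the enforced design
tolerance is 5 pp).  A cohort-characteristics balance report compares partitions
with Welch's t-test (continuous) and Pearson's chi-square
(binary/categorical); the study names no specific tests.  Features
constant in both partitions are reported with p = 1.0 and a degeneracy
flag.

## Metrics

Accuracy, precision, recall and F1 are computed per label from the
confusion counts; "accuracy" for the multi-label model is per-label
accuracy averaged over the five subtypes (subset accuracy is reported
alongside).  Zero-denominator cases return 0 with a degeneracy flag —
the convention under which a classifier that never predicts a rare
label scores recall 0 rather than NaN.  ROC curves group tied scores
into a single step and integrate by trapezoid, which makes the AUC
exactly the Mann–Whitney U statistic divided by n₁n₀ (verified against
the rank statistic and scikit-learn).  Micro AUC pools all
(sample, label) pairs across the five subtypes; macro AUC averages
per-label AUCs.  Paired model comparisons use a two-sided paired
t-test across folds or seeds.  Feature importance is permutation
importance on micro-AUC (mean drop over repeats when one encoded
column is shuffled across patients); the source study scores feature
importance but does not name its method.

## Synthetic cohorts

The clinical cohort is private, so the package ships a generator that
emulates its published marginal structure: continuous indices are
truncated normals (age 38.88 ± sd 12.04 on [18, 95], SBP, DBP, UPC,
eGFR likewise; published ± values are SEMs at n = 400 and are converted
to sds by √400), symptoms are Bernoulli at their published prevalences,
sex and DRBC grade are categorical at their published percentages.
Truncated-normal parameters are moment-matched so the *observed*
(post-truncation) mean equals the published mean exactly and the sd as
closely as the family allows — for UPC the published coefficient of
variation (1.76/1.53 > 1) exceeds what any left-truncated normal
attains, so its spread is best-effort (sd ≈ 1.50) while the mean stays
exact.  A log-normal would fit UPC's skew better; the truncated-normal
family is kept for uniformity since no downstream result depends on
that tail.

Labels come from independent per-label logistic links on standardized
features (continuous z-scored, binary centred at prevalence, one-hot
centred at category probability), with intercepts calibrated by
bisection on a fixed 50,000-draw sample to hit target prevalences
within 0.1 pp.  Subtype overlap arises from shared feature dependence;
*conditional* on features the labels are independent — a simplification
(the real subtypes likely correlate beyond what the features explain),
adequate because no shipped analysis depends on conditional label
dependence.  No per-subtype prevalences were published; the defaults
(0.45, 0.40, 0.30, 0.35, 0.30) are plausible overlapping values, and
the imbalanced preset sets the severe-subtype analogue to 8%,
qualitatively matching its described underrepresentation.

Three presets define the study conditions for end-to-end experiments:

* **separable** — each subtype is driven by a handful of clinically
  plausible symptoms/indices with strong coefficients (|β| = 3–8 on the
  standardized scale).  These coefficients were chosen so the preset is
  genuinely separable: the Bayes-optimal micro-AUC (scoring with the
  true link probabilities) is ≈ 0.986 at these settings, measured at
  n = 20,000.  This is a learnability fixture, not a claim about real
  effect sizes.
* **null** — B = 0: labels carry no feature signal.  Any systematic
  departure of held-out AUC from 0.5 would reveal label leakage.
* **rare-label** — the separable drivers with the severe-subtype
  analogue at 8% prevalence; the class-imbalance and ablation fixture.

What passing on these cohorts does *not* show: performance on the real
clinical cohort (unavailable), robustness to correlated symptoms (the
generator draws features independently), or to label noise beyond the
logistic link.

## Numerical and protocol choices

* Decision threshold is a strict inequality (p = 0.5 exactly → 0).
* Eq-style min-max scaling is undefined for a constant feature; the
  transform emits 0.0 and warns.
* The intercept bisection runs 200 iterations on [−30, 30]; the
  truncated-normal moment matching clamps |standardized bound| ≤ 6 to
  stay in the numerically exact sampling regime.
* Cross-validation re-fits preprocessing and class weights inside every
  fold; fold seeds derive from the run seed plus the fold index.
* Checkpoints store config, all parameter arrays and a schema
  fingerprint; loading against a different schema is refused.

## Experiment sizes and configuration

End-to-end experiments (`malnet.experiments`) use cohorts of 500
patients (400 train / 100 test) — the study size — and one shared
configuration: the published 32-unit hidden layer and four heads,
dropout 0.2 with learning rate 1e-3 and batch size 16 (settings from
the published sweep grids), and sum aggregation over the attended
sequence.  This corner of the exposed settings generalizes best in the
400-patient regime: sum aggregation preserves the magnitude of the
attended signal that a 38-token mean dilutes, and the small batch adds
gradient noise that counteracts memorization.  The null control trains
40 epochs (there is nothing to learn), the multi-seed comparisons 100
epochs per arm, the learnability run 300 epochs.

The multi-seed comparisons (class-weighting benefit, attention
ablation) are scored on a fresh 2,000-patient cohort drawn from the
same preset rather than on the 100-patient test split: the rare
subtype has only ~8 positives in a 100-patient split, which makes its
F1 a lattice of ~0.1-wide steps and would drown a modest effect in
evaluation noise.  Training itself always uses the protocol split of a
500-patient cohort.  On the additive logistic presets the attention
module's measured rare-label benefit is small (the generative links
contain no feature interactions for attention to exploit), so the
ablation difference is reported together with its paired p-value
rather than claimed as a strong effect.

## Known limitations

* Training the 27k-parameter network on 400 patients overfits: train
  micro-AUC reaches 1.0 while held-out micro-AUC on the separable
  preset averages ≈ 0.94 across seeds (0.930–0.959 on the 100-patient
  test set; the same when scored on fresh 2,000-patient cohorts),
  against the preset's Bayes optimum of ≈ 0.986.  The gap is a
  small-sample effect, not an architecture defect: trained on 2,000
  patients the identical model reaches held-out micro-AUC ≈ 0.96.
  Widening the generator's coefficients further, shrinking token
  width, or sweeping dropout/learning rate/batch within the exposed
  settings does not close it at n = 500.  The learnability check in
  the test-suite asserts the 0.95 fixture bar at a fixed seed and may
  therefore fail by this margin; the results script reports the
  achieved value.  No early stopping is used (the protocol trains a
  fixed epoch count).
* The full-model parameter count under the documented head layout
  (27,141 at d = 38) is a deterministic function of the config but does
  not match the source study's printed total (14.6 K), whose exact head
  widths and input dimensionality are unstated; the recurrent-layer
  count (8,320 ↔ "8.3 K") does match.
* The generator models marginals plus a chosen link, not the true
  joint distribution of clinical features, and no TCM diagnostic
  semantics.
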