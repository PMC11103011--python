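# Methods

## The analytic problem

Suicide death is rare and multi-determined. The design implemented here is a
matched case-control study over a healthcare-system population: cases are
patients whose underlying cause of death is a suicide code (ICD-10 U03,
X60–X84, Y87.0) before calendar 2018; controls are non-suicide patients
matched 1:1 without replacement on fiscal year of cohort entry and on the
year of the case's endpoint. All lookback features are computed from an index
date — the death date for cases, the first outpatient visit of the matching
year for controls — behind a 7-day buffer that excludes documentation of the
fatal event itself. A deep dual-stream classifier is fitted to case/control
status, and feature effects are then read off the fitted risk surface by
logit-mutation probing rather than from model coefficients.

## Synthetic cohort generator

Because the motivating data (a national EHR warehouse linked to death-index
records) cannot be shipped, `ehrisk.simulate` generates cohorts with the
statistical structure the analysis assumes. What it emulates:

* static demographics sampled from configurable categorical distributions
  (defaults shaped like a veteran population: 93% male, median birth decade
  1950s);
* enrollment as the first outpatient visit in the study window, extra visits
  as a Poisson process (2/year by default);
* temporal feature families as independent Bernoulli draws per 180-day
  lookback period (per-period incidences 0.002–0.03 by default), dated
  uniformly within their period behind a patient-specific endpoint date;
* a three-state disclosed LGBT status (2.3% Yes / 5% No / rest Unknown)
  realised as template note snippets — affirmative, negated and status-free
  templates designed to be separable by the rule set, with Unknown patients
  receiving no status-bearing note;
* the outcome as one Bernoulli draw per patient from
  `σ(β₀ + Σβⱼxⱼ + Σγⱼₖxⱼxₖ + β_age(age−61.6)/10)`, where `xⱼ` is presence of
  family `j` anywhere in the lookback (optionally weighted by the most recent
  period with an event when a recency-weight vector is supplied) or a static
  level indicator. The drawn linear predictor and probability are retained
  per patient, so any estimator can be validated against exact ground truth.

The endpoint-candidate date is drawn once per patient strictly after
enrollment; it becomes the death date when the outcome fires and the age term
is evaluated at it, which keeps the retained linear predictor exactly equal
to the sampling logit.

What the generator does **not** emulate: realistic ICD code frequencies and
co-occurrence, visit-intensity dynamics, informative missingness, clinical
prose, geography/urbanicity. Passing tests therefore demonstrate that the
estimators recover known structure under the stated sampling assumptions —
not that the pipeline is calibrated for any real population.

## Status extraction

`ehrisk.notes` implements the rule stage of a hybrid NLP pipeline: keyword
detection on word boundaries (so "gaylord" never matches "gay"),
case-insensitive positive and negative patterns with a keyword slot, and
negative-over-positive precedence within a note. Documents that match no
pattern abstain; in the original hybrid system those fall through to a
trained classifier, which is out of scope here — Abstain is a documented
fidelity gap, not an approximation of it. Patient-level aggregation is
any-positive over any-negative (disclosure-once semantics), with a
most-recent-note-wins policy available. The shipped keyword and pattern
inventory is illustrative; rule sets load from YAML.

## Matching

Matching runs over cases in seeded-random order, picking uniformly among
unused eligible controls (same enrollment fiscal year, at least one
outpatient visit in the endpoint year). A plain greedy pass can strand a case
whose only eligible controls were consumed by cases with wider choice, so a
stranded case triggers a randomized augmenting path (Kuhn's algorithm); the
result is always a maximum-cardinality matching, verified in tests against
brute-force bipartite matching on small random pools. Fiscal years follow the
US federal convention (1 Oct–30 Sep, labeled by ending year); the endpoint
stratum uses fiscal years by default and calendar years by option, since the
upstream convention is ambiguous. Unmatched cases are dropped with a warning.

## Encoding

* Time periods: `days_prior < 7` → excluded; `7 ≤ days_prior < 3607` → period
  `1 + (days_prior − 7)//180`; else period 21. The twenty slides cover 3,600
  days (≈9.86 y); "ten years and beyond" is operationalized as the residue.
* Static vector: fractional age at the index date (calendar-exact, leap-day
  birthdays anchored to 1 March) followed by n−1 dummies per categorical;
  the reference level is the most frequent, and Unknown LGBT status is a
  modeled level, not missingness.
* Temporal tokens: distinct `(feature_id, period_id)` pairs, sorted by
  (period, feature); sequences above 512 tokens drop the oldest periods.
* Vocabulary: drug-category codes need cohort prevalence ≥ 0.5% (inclusive);
  all other families are kept at any prevalence; id 0 is padding.

## Model

Temporal stream: feature-id and period-id embeddings combined by addition,
two post-layer-norm transformer encoder blocks (multi-head self-attention +
position-wise feed-forward, residual connections), followed by **sum**
pooling over real tokens. Sum pooling is deliberate: with mean pooling,
removing one feature's tokens rescales every other token's pooled
contribution, which injects a spurious negative component into every
mutation-probe interaction; with sum pooling token contributions stay
additive and an empty sequence contributes exactly zero, so the model then
reduces to the static stream. Static stream: standardized inputs through a
residual two-layer perceptron projected to the embedding width. The streams
are combined by element-wise addition and a fully connected sigmoid head
yields the risk score.

Training: binary cross-entropy (via a numerically stable
softplus-with-logits), Adam with decoupled weight decay on matrices, inverted
dropout, stratified 20% validation split. Model selection keeps the weights
with the best validation **cross-entropy** (patience 5 by default, metric
configurable to validation AUC). The proper scoring rule is used rather than
AUC because AUC is rank-based: it is nearly blind to the calibration of
small-population cells, and the mutation probes downstream consume exactly
that calibration. Per-epoch train/validation AUC is still reported, and the
operating threshold is the validation point where sensitivity and specificity
are closest to equal. AUC itself is computed by the Mann–Whitney rank
statistic with ties counted half.

Defaults: embedding 64, 4 heads, 2 blocks, MLP width 128, dropout 0.1,
weight decay 1e-4, learning rate 1e-3, batch 256, ≤30 epochs. The validation
experiments in `ehrisk.experiments` use a lighter instance (embedding 16, 2
heads, MLP 32, batch 512, learning rate 2e-3, ≤15 epochs) sized so a
20,000-patient recovery run finishes in a few minutes on one CPU; the
architecture (two encoder blocks, additive fusion) is unchanged.

The network runs on `ehrisk.autodiff`, a compact tape-based reverse-mode
engine over numpy arrays (broadcast-aware arithmetic, batched matmul,
softmax/softplus/layer-norm, embedding gather with scatter-add backward),
gradient-checked against finite differences in the test suite.

## Explainability

For a scorer `p(x)` and a patient, the impact of a feature is
`logit p_cur − logit p_ref` after mutating the feature to its reference —
absence for temporal families (all 21 periods at once by default; per-period
mutation is available), the all-zero reference level for a static dummy
block, 61.6 years for age. The impact score divides by the size of the value
change, in decades for age. Probabilities are clamped to `[1e-12, 1−1e-12]`
before the logit. Aggregation over a dataset is the mean over carriers
(patients whose current value differs from the reference); the upstream
definition is individual-level only, and the mean is this package's choice,
recorded in the output.

The interaction of two features compares the impact of mutating both with the
impacts of mutating each separately; the residual — equivalently, the excess
of the pair's joint effect over the sum of its solo effects measured from the
double-reference baseline, `impact_A + impact_B − impact_joint` — is the
interaction. For any scorer additive in the logit it is exactly zero, and for
a scorer with a product term `γ·x_A·x_B` it equals `γ` exactly for a patient
carrying both; both facts are asserted to 1e-9 in the tests and this sign
convention makes positive values mean "combined risk above the sum of the
separate risks". `rank_interactions` averages over patients carrying both
features and orders candidates by absolute mean interaction.

### What probing a fitted network can and cannot recover

Mutation probes report the fitted surface, not the data. Two regimes matter:

* Trained on the full simulated cohort at the generating index dates
  (n = 20,000, 30 features, planted β ∈ {+2, +1, −1}, planted γ = +0.8), the
  model recovers all impact signs, impact magnitudes within ~15%, and the
  planted interaction with the correct sign at rank 1 among 29 candidates.
* Trained on the matched case-control subset (~7,000 rows, control index
  dates displaced from the generating endpoint), the second-order structure
  is no longer learned at this scale: the model's own cell-mean logits show
  no interaction and the probes return curvature noise of roughly ±0.2,
  including between strong co-present main effects. Interaction estimates
  from small fitted transformers should therefore be read as exploratory
  rankings, not effect sizes.

The package's recovery validation accordingly trains on the full cohort —
isolating the estimator from design-induced attenuation, which the matching
stage's own invariants cover separately.

## Descriptive tables

Rates are displayed with half-up rounding at the conventional precisions
(all-cause mortality integer %, suicide mortality two decimals, suicide share
of deaths one decimal) with full-precision companions; every displayed rate
is recomputed from the counts in its own row. Case/control comparisons use a
chi-square test without continuity correction per categorical variable
(omnibus over levels) and Welch's t-test for age; the tests are reporting
plumbing, chosen here because the upstream convention names none.

## Pipeline

`ehrisk.pipeline.run` executes simulate → status → cohort/match → encode →
train → explain → report. One global seed fans out through a
`numpy.random.SeedSequence` (one child per stage, reduced below 2³¹); the
manifest records the configuration hash, stage seeds, row counts, timings and
SHA-256 checksums of every artifact, and a rerun with the same configuration
reproduces the checksums of all deterministic artifacts.

## Numerical and degenerate-input choices

* Probability clamping at 1e-12 before any logit.
* Empty token sequences are padded to length one with id 0 and masked out;
  pooled output is exactly zero.
* A patient pool that cannot supply controls yields unmatched cases with a
  warning, never an exception; a single-class training set raises.
* Categorical levels are ordered by frequency with alphabetical tie-breaks,
  making dummy layouts deterministic across runs.
* Duplicate rows in a prediction batch agree to BLAS summation order
  (≤1 ulp), not bitwise.

## Validation experiment sizes

Property suites run at 1,000 random toy cohorts (matching), 10,000 random
day offsets (period partition), 50,000 patients (single-feature log-odds
recovery), 20,000 patients × 3 seeds (planted-coefficient recovery), 4,000
patients (separable-cohort AUC and label-permuted null). The separable cohort
uses twelve features with β = 3 each plus a −0.5/decade age effect — a graded
risk score whose Bayes AUC is ~0.97 in both the full cohort and the matched
subset, which no single binary feature can reach (a binary predictor bounds
AUC by 0.5 + (P(x|case) − P(x|control))/2 ≈ 0.88 at best).

## Known limitations

* The rule-based status stage replaces the original hybrid system's
  machine-learned fallback with Abstain; recall on real prose would be lower.
* Presence-only temporal semantics: no counts, intensities or lab values.
* Interaction probes on matched-subset models are exploratory (see above).
* The simulator's independence assumptions (features independent across
  families and periods) make recovery easier than in real EHR data with
  correlated comorbidities.
* No calibration analysis, survival modelling or person-time rates.
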