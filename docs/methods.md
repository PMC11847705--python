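# Methods

## Overview

This package implements a transfer-learning framework for analysing small
multimodal clinical-omics studies. The setting: a large cohort of patients
has longitudinal coded EHR data and an outcome label; a much smaller
sub-cohort additionally has a tabular omics profile (e.g. plasma
proteomics) measured at a known sampling date. An EHR sequence encoder is
pretrained on the large cohort to predict the outcome from EHR alone; its
weights are then copied into a three-branch multimodal network and frozen,
and only the remaining weights are trained on the omics cohort. The frozen
encoder acts as a regularizer by initialization: the small-cohort model
starts from, and is constrained around, a representation fitted on orders
of magnitude more patients.

## Cohort construction

Events come from an OMOP-like extract restricted to the five clinical
event tables (measurement, observation, drug_exposure,
condition_occurrence, procedure_occurrence), with `concept_id = 0` rows
removed. Dates are integer day offsets; ISO dates are converted to
proleptic ordinals at load. Two windowing rules are implemented:

- **Pregnancy (days-to-labour-onset)**: windows start 280 days before
  delivery. Omics-cohort windows end at the sampling day; pretraining
  windows end at a day drawn uniformly (integer days, inclusive) from the
  100 days up to delivery, emulating the sampling design of the omics
  study. The label is days from the window end to delivery.
- **Cancer (3-year mortality)**: all history is kept up to the sampling
  day (omics cohort) or first-diagnosis day (pretraining cohort); the
  label is a provided binary indicator.

Patients whose window contains no events are retained with an empty
sequence (the encoder sees all padding); silently dropping them would
change cohort composition. A patient with several omics samples yields
several records that always travel together through any split.

## Embedding and sequence summarization

All codes recorded for one patient on one day form a "sentence"; the
within-day order is shuffled with a seeded generator because sub-day
timestamps in coded EHR data are unreliable. A skip-gram model with
negative sampling learns one vector per code (defaults: window 5, 5
negatives, min_count 1, 5 epochs, linearly decaying learning rate from
0.025; implemented in numpy, single-threaded, deterministic per seed).
Each day's summary is the arithmetic mean of its codes' vectors;
out-of-vocabulary codes are skipped rather than zero-imputed (zero vectors
would bias day means toward the origin), and days with no embeddable codes
are dropped without counting toward the cap. The encoder consumes at most
the 32 most recent summary days, oldest first, front-padded with zero rows
plus a validity mask.

The reference configuration uses 400-dimensional embeddings; desk-scale
experiments here use 16 so that the full study runs in minutes on one CPU.

**Embedding spaces and transfer.** Training one embedding model per cohort
is supported (`tables_for_bundle(..., shared=False)`), but skip-gram
solutions are only defined up to rotation, so a frozen encoder trained on
one cohort's space is not meaningful on an independently trained space.
The experiment protocol therefore defaults to a single table trained on
the pretraining corpus and applied to both cohorts.

## Architecture and losses

The multimodal network has three branches producing raw scalar scores:

- **EHR branch** — a stacked GRU over the day-summary sequence (padded
  positions leave the hidden state untouched); an affine head maps the
  final hidden state h to a score.
- **Omics branch** — an affine head on the omics vector (regression) or a
  one-hidden-layer perceptron with rectifier activation (classification;
  hidden size from {16, 32, 64}).
- **Joint branch** — an affine head on the concatenation [h, omics].

A final bias-free linear layer mixes the three scores; regression returns
the mix directly (MSE loss), classification passes it through a logistic
link (BCE loss with a 1e-7 clamp on predictions). Combining the branch
scores on the logit scale keeps the combiner linear for both tasks. The
single-branch baselines are exactly the corresponding sub-networks: the
network with a unit-vector combiner reproduces them prediction-for-
prediction, which is asserted in tests.

An alternative transformer encoder is provided: day-wrapped token streams
(sequence-start / day-start / day-end specials, within-day shuffle, max
length 1024 with oldest tokens dropped), learned token embeddings scaled
by sqrt(d) plus sinusoidal positional encodings, and two post-norm encoder
layers (4 heads, 512-dim feed-forward); padded keys receive a large
negative additive attention score, and the latent state is taken at the
last non-padding position (a padding position would read a masked token).

## Training, transfer, protocol

Optimization is adaptive moment estimation with a per-epoch multiplicative
learning-rate decay `lr_e = lr0 * (1 - decay)^e`, minibatches of 512
(pretraining) / 16 (omics cohort), early stopping when the held-out loss
has not improved for 5 consecutive epochs, and restore of the best epoch.
Pretraining holds out 20% of pretraining patients (grouped) for early
stopping. On transfer, the encoder weights are copied and frozen — tests
assert they are bitwise identical after any amount of multimodal training
— while the pretrained EHR head is copied as a trainable initialization
(freezing it is not required for the regularization effect and would
prevent the head from recalibrating to the omics cohort). A fully frozen
encoder makes the latent states constants, so multimodal training caches
them and trains only the heads; this is an exact reformulation, not an
approximation.

Evaluation uses 25 repeated patient-grouped 70/15/15 splits; per repeat,
models train on the 70% (early-stopping on the 15% test split) and predict
the 15% validation split; a record's final prediction is its mean over the
repeats in which it was in validation. The same protocol drives the
prior-informed linear baselines (`mode="prior_ridge"` /
`"prior_logistic"`): their (strength, gamma) is chosen once by grouped CV,
then each repeat refits on the train + test patients and predicts
validation. Metrics: Pearson r (t-distribution
p-value), r.m.s.e., Lin's concordance for regression; AUROC, AUPRC and
Cohen's kappa (threshold 0.5, configurable) for classification. Confidence
intervals are seeded nonparametric percentile bootstraps (1000 resamples)
over prediction pairs — metric-agnostic and assumption-light.

Dropout follows the standard stacked-GRU convention and acts between
recurrent layers only; the prediction heads are dropout-free (for a fully
frozen encoder, dropout therefore has no effect on head training, which
is intended — the regularizer there is the frozen representation itself).

Optimization hyperparameters are selected once, before the repeated
splits, by grouped 3-fold cross-validated grid search (20% of each
training fold held out for early stopping; minimum mean validation loss;
ties keep the first grid point), and then fixed; pretraining keeps its own
base schedule. On the default synthetic cohort this selection chose
learning rate 1e-2 for every mode, with per-epoch decay 1e-2 for the
transfer modes, 1e-1 for the joint and omics-only baselines (the joint
baseline with dropout 0.1) and 1e-3 for the EHR-only baseline; encoder
depth 2 beat 4 on pretraining validation loss. These are the package's
per-mode defaults (`eval_harness.MODE_DEFAULTS`), applied automatically
by `run_protocol` to the omics-cohort training stage.

## Prior-informed linear baselines

Ridge regression minimizes `||y - Xb||^2 + lambda ||b - gamma b0||^2`
(closed form `(X'X + lambda I)^{-1} (X'y + lambda gamma b0)`), and
logistic regression minimizes the negative log-likelihood plus
`(1/2C) ||b - gamma b0||^2` by damped Newton-Raphson (convergence when the
penalized gradient norm falls below 1e-6, at most 100 iterations;
non-convergence is flagged, not raised). `b0` comes from an EHR-only model
fitted on the pretraining cohort with the same preprocessing recipe, and
is exactly zero for features absent from pretraining (all omics columns).
Features are one-hot EHR occurrence indicators plus omics columns,
filtered at raw variance 0.01 *before* standardization (afterwards the
filter would be vacuous), then standardized. An unpenalized intercept is
fitted by default — shrinking the intercept toward 0 or b0 is rarely
intended — with `fit_intercept=False` available to solve the printed
objective verbatim. Grouped 3-fold CV selects (strength, gamma) by minimum
mean r.m.s.e. (regression) or maximum mean AUROC (classification); grouped
splits are also the default for the logistic model (random splits are
available via `grouped=False`), and held-out fold predictions are
concatenated for evaluation.

## Interpretation suite

- **Integrated gradients** on the omics vector, with the record's own EHR
  sequence held fixed and a zero baseline (the cohort mean on standardized
  analytes). The path gradient is averaged at the m midpoints
  `(s - 1/2)/m` (default m = 128), making the completeness identity
  `sum(attr) = f(x) - f(baseline)` hold to O(1/m^2) for smooth models;
  the endpoint-rule alternative is O(1/m) and noticeably looser at the
  same m. For the classification network the rectifier head introduces
  derivative discontinuities along the path, degrading any quadrature to
  O(1/m) — tight completeness there needs m in the thousands, while the
  regression network is linear in the omics input and satisfies the
  identity exactly. Per-analyte importance is the mean absolute
  attribution.
- **Latent-analyte alignment**: all latent-dimension x analyte Pearson
  correlations with Bonferroni correction over the full d x P family (the
  conservative reading); constant columns are reported non-significant.
- **Correlation maps**: each feature's row of the full signed correlation
  matrix is embedded in 2-D by t-SNE (fixed seed, perplexity reduced
  automatically for small feature sets), with per-feature outcome
  correlations, Bonferroni-significant cross-modality pair counts per
  analyte, and each EHR feature's maximum absolute correlation over
  analytes.
- **Intermediate nodes**: each branch score evaluated directly against the
  outcome (Pearson r / AUROC).
- **Function-space trajectories**: per-epoch snapshots are compared by
  their concatenated outputs over a fixed record set (overall prediction
  and each branch score as separate views), embedded in 2-D — networks
  with different parameters can be functionally identical, so parameters
  themselves are not compared.

## Synthetic cohorts

Real cohorts of this design are access-restricted, so a generator supplies
study-shaped data. Each patient has a latent state z ~ N(0, I_k) driving
(i) daily code emission, Bernoulli per code per day with probability
`logistic(u_c . z + b_c + delta_t)` where b_c sets the base rate and
delta_t ramps linearly toward the anchor day (codes intensifying toward
delivery/diagnosis); (ii) omics x = A z + eps per sample; (iii) the
outcome, `w . z + eta` (continuous, ||w|| = 1) or Bernoulli through a
logistic link whose intercept is solved by root-finding to hit a target
prevalence. Omics patients get 2 sampling days within the last 10 days of
the 20-day horizon; pretraining records cut their history at a random day
in the same span, mirroring the two windowing rules. Code emission is
Bernoulli presence rather than counts because the embedding pipeline only
consumes within-day presence.

Default scale: 2000 pretraining patients, 80 omics patients, 200 codes, 50
analytes, k = 4 — small enough that the full four-mode comparison runs in
minutes on one CPU. The free noise parameters were set once so the
synthetic study reproduces the qualitative structure of the real ones —
EHR-only the weakest baseline, omics-only slightly better, the joint
baseline best, and the transfer model on top, with omics informative but
well below the noise ceiling: code_base_rate 0.01, omics_noise 1.2,
outcome_noise 0.5, loading_scale 1.0. `oracle_r2` returns the population
variance ceiling `||w||^2 / (||w||^2 + outcome_noise^2)` (0.8 at the
defaults, i.e. a Pearson ceiling of ~0.894) for calibrating how much
headroom any model has.

What the generator does **not** emulate: realistic OMOP vocabularies or
code frequency distributions, visit structure, informative missingness,
measurement batch effects, censoring, or nonlinear latent-outcome maps.
Passing tests therefore show that the machinery behaves as specified under
a faithful latent-factor model of the study design, not that the method's
quantitative gains carry to any particular real cohort.

## Numerical choices and limitations

- All randomness flows through seeded `numpy.random.Generator` instances;
  protocols, embeddings and training are reproducible bit-for-bit per
  seed.
- The neural components (autodiff tensor engine, GRU, transformer layers,
  Adam, skip-gram) are implemented in numpy and verified against
  numerical gradients in the test suite; they target the desk-scale
  configurations used here, not GPU-scale workloads.
- BCE clamps predictions at 1e-7; the logistic Hessian is ridge-protected
  and Newton steps are halved until the objective does not increase.
- Early-stopping ties (no strict improvement) count toward patience;
  grid-search ties keep the first point in grid order.
- Degenerate inputs: empty windows give all-padding sequences; constant
  predictions make Pearson r undefined and are reported as missing;
  single-class CV folds are skipped with a warning.
- The 25-repeat protocol at 80 patients leaves each record in validation
  ~3.75 times on average; records never sampled into validation are
  excluded from metrics with a logged count.
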