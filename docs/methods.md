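# Methods

## Problem setting

Multi-center neuroimaging studies pool 3D brain scans acquired on different
MRI scanners. When a classifier is trained across such a cohort, scanner
signatures (intensity gain, offset, resolution, noise spectrum) correlate
with center membership and — because disease prevalence varies by center —
with the diagnosis itself. The classifier can then exploit the scanner as a
shortcut, which destroys generalization to new sites.

The *traveling model* (TM) is a sequential distributed-learning scheme: a
single model visits one center at a time, trains for one local epoch on the
center's own data, and moves on; a *cycle* ends when every center has been
visited, and the center order is re-randomized every cycle. It suits
cohorts where many centers hold only a handful of scans — too few for
federated averaging or for any harmonization method needing large or paired
local datasets.

This package implements adversarial scanner *unlearning* embedded in the
traveling schedule. The network is an SFCN-style 3D convolutional encoder
with two heads sharing its flattened feature vector:

* a disease head — one dense unit, sigmoid output;
* a scanner head — one dense layer, softmax over the M scanner types.

## Losses

With batch size N (whatever the visited center can supply, at most 5),
disease labels y, disease probabilities p, one-hot scanner labels Y and
scanner softmax P:

* disease loss `L_pd = -(1/N) Σ_n [y_n log p_n + (1-y_n) log(1-p_n)]`
* scanner loss `L_sc = -(1/N) Σ_n Σ_j Y_nj log P_nj`
* confusion loss `L_conf = -(1/(N·M)) Σ_n Σ_j log P_nj`
* logged total `L_total = L_pd + L_sc + L_conf`

The confusion loss is the cross-entropy of the scanner softmax against the
uniform distribution; by Gibbs' inequality it is bounded below by `ln M`,
attained exactly when every row of P is uniform — i.e. when the scanner
head is at chance. All probabilities are clipped at `1e-7` inside
logarithms. The `1/N` normalisation makes every loss batch-size aware, so
centers contributing fewer than five scans are neither re-weighted nor
oversampled: each batch is used exactly as the center provides it.

## Three-step procedure

After two-phase pre-training (below), every batch at every visited center
undergoes three sequential sub-updates:

1. encoder + disease head descend `L_pd`;
2. scanner head descends `L_sc` on *frozen* encoder features (the encoder
   forward runs in evaluation mode, so not even a batch-norm byte moves);
3. encoder alone descends `L_conf` through the frozen scanner head.

Steps 2 and 3 are an adversarial game: the head re-learns to read scanner
identity from the features, and the encoder then removes whatever the head
found. Each sub-update has its own Adam state over exactly the parameter
group it may touch; the freeze contracts are bitwise and tested. `L_total`
is reported per batch as a diagnostic. An alternative single combined
encoder update (disease + confusion gradient applied at once) is available
behind a flag; the sequential form is the default because only the
alternating form keeps the adversary's objective well-posed.

Pre-training runs in two phases on the same traveling schedule: (A) encoder
+ disease head until the task loss plateaus, then (B) scanner head on the
frozen encoder. "Until convergence" is realized as a fixed cycle budget with
optional early stopping on a loss plateau (configurable patience), which
keeps desk-scale runs reproducible.

Before each evaluation the experiment driver runs a short disease-head-only
convergence pass on the frozen encoder (`disease_only` mode, the exact
analogue of phase B for the scanner head, two cycles by default).  In
sequential training the head's bias tracks the class balance of the last
centers visited — single-class centers push it hard — so without this pass
the fixed-threshold accuracy measures the visiting order, not the
representation.  The pass touches only the disease head (bitwise-tested)
and therefore cannot alter any leakage measurement.

## Traveling loop and optimizer policy

Per cycle: a seeded permutation of centers; per center: a seeded local
shuffle and a batch plan of `[5, 5, ..., remainder]`. Learning rates decay
exponentially per cycle (default factor 0.95; the TM default initial rate
is 1e-4, the centralized baseline's is 1e-3). Optimizer state travels with
the model across centers and cycles — the model object is what travels — a
per-center reset is available behind a flag.

Two learning-rate scales matter for the adversarial game and default to
values chosen once during development at desk scale:

* `lr_scanner_scale = 30` during harmonization: the single-layer adversary
  is trained online on tiny single-center batches and must stay competitive
  with the encoder, otherwise the encoder merely fools a stale head while a
  freshly fitted probe still reads scanner identity from the features;
* `lr_scanner_pretrain_scale = 10` for phase B, where the head only needs
  to converge on a stationary encoder and a larger rate destabilizes it;
* `lr_confusion_scale = 3`: the unlearning step moves faster than the task
  step, so disease fitting cannot continuously re-introduce the confound.

The centralized baseline shares every step function with the traveling
loop; it differs only in drawing shuffled batches of five from the pooled
cohort, so batches may mix centers.

## Synthetic cohort generator

Each sample volume is `phantom × subject-jitter (+ disease shift inside a
mask) → scanner effect → acquisition noise`:

* **Phantom**: a fixed superposition of 12 Gaussian blobs drawn from the
  cohort seed, float32 intensities in [0, ~2]; no normalization.
* **Subject jitter**: a per-sample global amplitude factor
  `N(1, 0.05)` emulating inter-subject anatomical variability; without it
  every (scanner, class) cell collapses to a point and separability becomes
  a discontinuous function of thresholds.
* **Disease effect**: an additive shift `disease_delta` inside a spherical
  mask (radius ≈ extent/6, slightly off-center).
* **Scanner effect**: per scanner type, Gaussian blur (`smooth_sigma`),
  multiplicative `gain`, additive `offset`, and scanner noise, all scaled
  by a global `confound_strength` (0 = identity).
* **Acquisition noise**: i.i.d. Gaussian, default sd 0.05.

The desk-scale study cohort has 16 centers, 4 scanner types, 320 samples of
24³ voxels: four centers with fewer than five samples, five single-class
centers, two centers operating two scanners — the structural quirks of real
multi-center disease databases. `disease_delta = 0.065` was calibrated once
so that the *mask-contrast oracle* (threshold on mean-inside-mask minus
mean-outside-mask, which cancels global offsets) reaches ≈80% accuracy
under the full confound; the scanner-effect pool spans gains 0.85–1.15,
offsets ±0.1, blurs 0–0.75 voxels.

What the generator does **not** emulate: MRI physics, anatomy, spatial
disease patterns beyond a single blob, scanner drift over time, or
demographic covariates. Passing tests therefore demonstrate that the
procedure removes *linearly decodable global acquisition signatures* while
preserving a *localized intensity signal* — the mechanism, not clinical
performance.

## Evaluation and the representation audit

Disease metrics: accuracy at threshold 0.5, AUROC, sensitivity,
specificity, precision, F1. Scanner metrics: per-class one-vs-rest metrics
averaged with support weights (multiclass specificity is defined
one-vs-rest, then support-weighted), plus the M×M confusion matrix (rows =
actual).

Scanner *leakage* is measured by an independent logistic probe
(ridge-regularised, C = 1) fitted on training-split encoder features and
scored on the held-out split — deliberately not by the model's own scanner
head, which the encoder has been trained to fool. The PCA audit projects
the pooled (train + test) features onto their first two principal modes and
fits held-out logistic probes per mode and jointly, for scanner and disease
labels. Probes always score on data they were not fitted on (seeded 80/20
stratified split); fully collapsed feature representations fall back to
majority-class accuracy, the correct "no information" answer.

## Experiment orchestration

`run_experiment` evaluates the 2×2 of {traveling, centralized} ×
{before, after harmonization} on one common test split: per-(center, class)
stratified 80/20, with singleton strata kept in training. "Before" is the
task-pretrained model with the scanner head fitted on frozen features;
"after" follows the adversarial cycles (desk-scale budgets: 10 task
pre-training cycles, 4 scanner-head cycles, 8 harmonization cycles —
chosen as the smallest budgets at which the task loss plateaus and the
adversarial effect is stable across seeds). All randomness descends from
one seed.

## Numerical choices

* Volumes are standardised per volume (z-score) at the encoder input in the
  desk configuration — the usual first step of volumetric CNN pipelines.
  It removes global gain/offset analytically, which both stabilises
  optimisation and leaves the harder, textural part of the scanner
  signature (blur, noise spectrum) for the adversarial procedure to deal
  with.  The raw-intensity path (`normalize="none"`) remains the library
  default for generic use.
* During the three-step procedure all forwards default to classic training
  behaviour (per-batch batch-norm statistics).  Two alternatives are
  implemented and switchable — `inference_stats=True` (steps 1 and 3 on
  frozen running statistics) and a `running` batch-norm policy (normalise
  by running statistics while still tracking batch ones) — because with
  single-center batches of at most five samples the training-time and
  inference-time representations can diverge substantially.  Both
  alternatives unlearn the inference-time representation more aggressively,
  but the backward pass through low-variance normalisation layers amplifies
  the confusion gradient by orders of magnitude, which at desk scale
  destabilises the disease task; they are therefore off by default.
* Max/avg pooling use floor division; a spatial axis that has collapsed to
  extent 1 passes through further pools unchanged, so the full block stack
  accepts desk-scale inputs; the kernel-2 average pool with this skip rule
  is what yields exactly 768 features at 160×192×160 (5×6×5 → 2×3×2 cells ×
  64 channels), whereas global pooling would give 64.
* Channel widths default to the canonical SFCN set (32, 64, 128, 256, 256,
  64) and shrink to (4, 8, 16, 32, 32, 16) for desk-scale runs.
* Batch-norm statistics are part of the model state and travel with it;
  they are *staged* during training forwards and committed only when an
  optimizer step actually updates the model, so a zero learning rate leaves
  the bundle bit-identical.
* Gradient correctness of the hand-written backward passes is verified
  against central finite differences in the test suite.
* He initialization, seeded; probability clipping ε = 1e-7; Adam defaults
  β = (0.9, 0.999).

## What harmonization achieves at desk scale — and what it cannot

Across seeds, the adversarial cycles drive the model's own scanner head to
chance-level accuracy, keep or improve disease accuracy and AUROC, and
reduce scanner separability in the per-batch confusion loss to near its
ln M bound.  An *independent* logistic probe refitted to convergence on the
final features, however, retains scanner accuracy well above chance.  Two
effects cap how far any method can push that probe on this cohort:

* **Leakage through the label structure.** Center prevalence correlates
  with scanner type (single-class centers run particular scanners — a
  structural feature of real multi-center disease databases that the
  generator reproduces on purpose).  A probe given only the *ideal*
  disease representation (the true label plus the mask-contrast statistic)
  already identifies the scanner at ≈0.41 accuracy on the desk cohort.  A
  disease-preserving encoder therefore cannot reach the 0.25 chance level;
  the confound and the signal are statistically coupled at the cohort
  level, not merely in the features.
* **Adversary staleness.** The sequential game only removes what the
  online scanner head has currently found; a post-hoc probe fitted to
  convergence can find more.  Strengthening the adversary (larger head
  rates, inner iterations, inference-statistics unlearning) closes this
  gap but, at 320 samples and 16 features, destabilises the disease task
  before the gap closes — the aggressive variants are implemented and
  switchable, with this trade-off as the documented reason they are not
  default.

The package therefore reports both leakage measures (own head and
independent probe) side by side; conclusions about harmonization strength
should always cite which one they use.

## Known limitations

* The adversary is linear; nonlinearly encoded scanner information is
  outside the audit's reach (as it is for the linear-probe audit itself).
* Desk-scale budgets are tuned for 24³ volumes and a 4-type scanner pool;
  the full-resolution configuration is exercised for shape contracts only.
* The plateau-based early stopping is a pragmatic stand-in for
  "training until convergence", which is under-specified in sequential
  training where the data distribution shifts at every center visit.
* In-process center hand-off simulates model travel; no transport,
  encryption, or multi-host orchestration is provided.
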