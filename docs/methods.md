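# Methods

## The problem

Very preterm infants (born at ≤ 32 weeks gestational age) are at high risk
of cognitive, language and motor deficits that only become measurable at
around two years corrected age (Bayley-III score ≤ 85 defines the high-risk
class here). The modelling question is whether those outcomes can be
predicted at term-equivalent age from the functional connectome — the
90 × 90 matrix of Pearson correlations between ROI BOLD signals — optionally
fused with routine clinical variables. The obstacle is sample size: labeled
target cohorts number in the tens, while deep networks want thousands.

`mmdtl` implements the staged transfer strategy that addresses this:

1. **Stage 1 — supervised pre-training** of a 5-layer classifier (ReLU
   hidden units, batch normalization, 2-unit softmax head) on a large
   labeled source cohort from a different population (hundreds of subjects,
   a different classification task, multi-site).
2. **Stage 2 — unsupervised adaptation**: the source network's hidden
   layers initialize the encoder of a 9-layer mirror-symmetric autoencoder
   (sigmoid output, per-feature cross-entropy reconstruction) trained on an
   unlabeled intermediate cohort drawn from a population closer to the
   target.
3. **Stage 3 — multi-task fine-tuning**: encoder plus bottleneck initialize
   the trunk of a 7-layer multi-task network with C independent 2-unit
   softmax heads, optionally concatenating an encoded clinical vector onto
   the bottleneck representation, trained on the small labeled target
   cohort with the weighted objective

   J = −(1/(mC)) Σ_c α_c Σ_i β_ic [ y_ic log p_ic + (1−y_ic) log(1−p_ic) ]

   where β_ic up-weights minority-class samples by the majority/minority
   count ratio of the training split (computed per task on the training
   split, never per batch and never using held-out data) and α_c weights
   task c (default 1).

All computation is numpy with hand-written backpropagation, including the
batch-normalization backward pass in both batch-statistics and
frozen-statistics modes.

## Connectome and clinical features

Connectivity is the Pearson correlation of ROI time-series columns; the
strict upper triangle in row-major order (length n(n−1)/2; 4005 for 90
ROIs) is the model input, affinely rescaled from [−1, 1] to [0, 1] in every
stage so the autoencoder's per-feature cross-entropy target is valid. The
vectorization order is fixed and stored with every saliency output, so edge
rankings are invertible to ROI pairs.

Multi-site source collections are harmonized by per-site, per-feature
z-scoring (the simplest documented, reversible choice; the statistics are
fitted on training data and reusable). Correlations are used raw — no
Fisher z-transform by default.

Clinical tables are encoded by a fitted, reusable transform: continuous
columns median-imputed and standardized with fitting-split statistics
(zero-variance columns encode to 0 with a warning), binary columns mapped
to {0, 1} by sorted level order, categoricals one-hot over the fitted level
set. Inside cross-validation the transform is refitted on each training
fold.

## Training protocol

Plain mini-batch SGD at learning rate 0.01 with stage defaults of
batch 32/100 epochs (stage 1 — a package choice), 16/50 (stage 2) and 4/10
(stage 3), early-stopped when the validation loss is flat for 3 consecutive
epochs (pairwise within tolerance 1e−4; tolerance 0 reproduces the literal
equal-loss rule). The validation split is a seeded stratified 20% of each
stage's training data (stratified on the rarest task's labels in stage 3).
Probabilities are clipped at 1e−7 before logs. Two numerical safeguards are
config-exposed: a global per-batch gradient-norm ceiling (default 5.0) and
optional L2 weight decay (default off). Everything is deterministic given
(config, seed); batch order is a function of (seed, epoch).

Transfer maps copy only shape-compatible, representation-bearing layers:
stage-1 hidden layers → autoencoder encoder layers 1–3; encoder layers 1–4
(through the bottleneck) → stage-3 trunk; stage-1 hidden layers → stage-3
trunk layers 1–3 in the single-stage variant. Mapped layers may optionally
be frozen during later training.

## Benchmark configuration

The benchmark experiments (`mmdtl.experiments`) run the full framework on
synthetic cohorts at widths (128, 64, 32, 16) — layer widths throughout the
package are configuration, not protocol — with cohort sizes 400/200/33 for
the training-heavy comparisons and 884/291/33 for saliency recovery.
Several training choices differ from the package defaults, each made
because fine-tuning 26 subjects in 90 SGD steps atop lightly trained
encoders is otherwise dominated by noise:

* pre-training runs to convergence: stage-1/2 learning rates 0.1/0.2 over
  30/40 epochs with weight decay 0.01 and a first-layer initialization
  gain of 0.02. Under the short default schedules, encoder quality — and
  hence every downstream comparison — is a per-seed lottery; weight decay
  shrinks the weight components no data gradient supports, and with batch
  normalization the network function is nearly invariant to the input
  layer's scale, so a small initial gain lets its learned component
  dominate the random initialization sooner without changing what the
  network computes.
* transferred layers are frozen during stage 3 (feature-extraction
  transfer). Full fine-tuning of a 4005-input trunk from 26 samples
  destroys the transferred representation before the heads can use it.
  The one exception is the multi-task-versus-single-task comparison,
  whose mechanism — joint labels regularizing a shared representation —
  requires the trunk to train; that experiment fine-tunes all layers at
  learning rate 0.05.
* stage-3 batch normalization uses frozen running statistics calibrated on
  the training split (and recalibrated each epoch as weights drift).
  Batch statistics of 4-sample batches are mostly noise; calibrating on
  the target split also adapts transferred statistics to the new domain.
* the stage-3 learning rate is 0.2 in the frozen-trunk benchmarks (the
  package default stays 0.01): with heads training from scratch for only
  10 epochs on 26 samples, the protocol learning rate leaves them at
  their random initialization.
* α_c = C, the multi-output convention in which per-task losses sum rather
  than average; it also gives joint and single-task models identical
  per-task effective step sizes, which keeps the multi-task comparison
  fair.

A measured limitation: at 33 target subjects the joint-versus-single-task
AUC difference is small (~+0.01 to +0.03) against per-seed cross-validation
noise of ~0.06–0.08, so 20-seed runs resolve it only in favorable draws;
demonstrating it reliably would need on the order of a hundred seeds.

## The synthetic cohort generator

The generator emulates the statistical structure the framework assumes,
not BOLD physiology. Edges arise from an 8-factor linear model squashed by
tanh(0.25·raw), giving correlation-valued features concentrated in the
realistic |r| ≲ 0.8 band:

* factors 0–2 are task-specific outcome factors, factor 3 a shared outcome
  factor, factors 4–7 background; all have dense N(0, 0.4) loadings, so an
  autoencoder has reconstruction-variance reasons to encode every one of
  them — the premise that makes unsupervised adaptation transferable.
* each outcome factor's loadings are boosted by ±3.0 on its planted edge
  support: 9 common edges (shared factor) plus 11 task-specific edges per
  task, i.e. 20 planted edges per task with the overlap structure reported
  for real cohorts. Planted edges are thereby the individually most
  discriminative edges.
* target labels: a shared liability u plus task noise (correlation 0.6)
  is thresholded by exact counts — 5/7/5 positives among 33 at the
  documented 15/21/15% prevalences — and positives are shifted by
  δ = 4.0 along the shared factor (scaled by each subject's overall risk
  load) and 0.25·δ along their task factor. The shared-dominant split
  reflects the clinical reality that the three deficits co-occur through
  common pathways, and it is precisely the structure that makes joint
  multi-task training informative; with fully private per-task signal,
  single-task specialization wins instead. δ is anchored so the
  Bayes-oracle AUC of the simulated outcome problem (~0.86 at large n)
  matches the best published model AUC, which the real cohort's
  separability must have at least supported.
* the cohorts realize a two-hop domain geometry: the adult/source domain
  and the neonatal domain (intermediate + target) share the planted
  boosts, but their dense factor structures overlap only with cosine
  `source_neonate_sharing` = 0.5 — the gap the unsupervised adaptation
  stage exists to bridge. The source cohort (17 sites, additive per-site
  N(0, 0.3) edge offsets, exactly half positive) shifts all outcome
  factors for positives; the intermediate cohort is unlabeled with a
  shifted factor mean. A `latent_sharing` dial blends the target's dense
  structure with the neonatal domain's; at 0 the pre-trained
  representation is (nearly) uninformative about the target — the
  negative control of the transfer-benefit experiment.
* the clinical table has 84 mixed-type columns (60 continuous, 16 binary,
  8 three-level categorical, ~2% missingness): 10 continuous columns track
  the latent risk, 5 are site-correlated decoys, the rest noise.

Exact-count labels (not Bernoulli draws) keep tiny-cohort tests
deterministic in class composition. What the generator does **not**
emulate: temporal autocorrelation of BOLD, SPD geometry of correlation
matrices (edges are generated directly and clipped by tanh), realistic
site-by-covariate confounding, or measurement differences between scanner
platforms. Passing benchmarks therefore demonstrate that the
implementation realizes the claimed statistical mechanisms, not that the
method will attain any particular accuracy on real infants.

## Evaluation

Repeated stratified 5-fold cross-validation (default 50 iterations, each
re-splitting with a fresh seed): stages 1–2 never see target data and are
trained once; stage 3 and every target-side transform are refitted per
fold. Per iteration, per-fold metrics are averaged (a pooled-prediction
mode is available; with 6–7-subject folds per-fold sensitivities are
coarse, and both modes are reported in the literature); mean ± SD over
iterations summarizes. Metrics: balanced accuracy, sensitivity,
specificity, LR+ (= Sen/FPR, +∞ when FPR = 0), FPR and rank-based AUC,
with BA = (Sen+Spe)/2 and FPR = 100 − Spe holding exactly at full
precision; display rounding is half-up to one decimal (two for AUC). Folds
are stratified on the rarest task's labels — with 5 positives among 33,
unstratified folds can be single-class and leave sensitivity undefined
(`stratify=False` restores the literal random split). Model comparison is
a two-sided t-test on iteration-level values, Welch by default (a pooled-
variance flag exists). Classification threshold is 0.5 on the
positive-class probability.

## Saliency

Importance of edge a_ij (or clinical feature e_i) for task c is the
absolute partial derivative of the task's positive-class probability with
respect to that input — |∂p_c/∂a_ij| — averaged over a reference set
(default: the target training subjects), computed by backpropagation with
evaluation-mode batch normalization so the map is deterministic. A logit-
target mode divides out the p(1−p) factor. Top-k lists break ties by fixed
feature order; overlap reports intersect the per-task top-k sets for every
task subset.

**Limitation (measured, not hypothetical):** at the 33-subject study
conditions the fine-tuned per-task readout is dominated by sampling noise
in the transferred representation, and gradient saliency does not reliably
concentrate on the planted discriminative edges (their median rank sits
near the middle of the 4005 edges; recovery improves markedly at a few
hundred target subjects). Two structural effects compound this: per-sample
|gradients| carry heavy ReLU-gating noise that survives averaging of
absolute values, and any variance-sensitive readout discounts
high-variance (strongly loaded) edges. The saliency machinery itself is
verified against finite differences and against closed-form linear
models, and recovers an oracle-aligned input layer at the 0.2nd
percentile; the barrier is statistical, not a defect of the gradient
computation. Interpretations of top-k lists fitted on tens of subjects
should be treated accordingly.

## Numerical choices

Batch normalization: momentum 0.9, epsilon 1e−5, placed after each fully
connected hidden layer. Initialization: uniform(±√(6/fan_in)), zero
biases; bit-identical given (architecture, seed). Softmax is computed with
max-subtraction; per-task head probabilities sum to 1 within 1e−9 or an
error is raised. The autoencoder objective implements exactly the printed
reconstruction cross-entropy; an optional sparsity penalty is deliberately
omitted from the default (the printed objective has none). In the printed
stage-3 objective the task weight appears outside the task sum; it is
implemented inside the sum, the only reading under which tasks can be
weighted differently. LR+ is reported as +∞ (JSON sentinel) at FPR = 0.
Stage-3 early stopping monitors the validation loss with unit β so the
monitored quantity is comparable across class balances.
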