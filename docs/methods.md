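# Methods

## The question and the design

Brain-age models are trained on large healthy cohorts to predict
chronological age; the brain age gap (BAG = predicted − chronological age)
is then used as a marker of accelerated aging. Whether a brain-age-derived
predictor can beat a classifier trained *directly* on the clinical label is
an empirical question about how much task-relevant information survives the
age-prediction bottleneck. This package operationalizes that comparison as
a pipeline of five AD-classification approaches and three MCI-progression
approaches over repeated nested splits of age/sex-matched cohorts, with the
corrected resampled t-test as the comparison statistic.

Real AD cohorts (multi-site, access-controlled) are out of scope; a
generative model of multi-site structural volumes stands in for them. Every
claim the test suite makes is therefore a claim about the generator's
world; the section on the generator below states what that world does and
does not capture.

## The synthetic cohort generator

A subject's volume is rendered as

    clip(template
         + a_age · (age + η − age_ref) · P_age
         + a_dis · s · P_dis
         + offset_scanner + gain_scanner · template
         + ε, 0, 255)    → rounded to 8-bit integers

* `template` — a fixed bright-ellipsoid-on-dark-background "brain";
* `P_age` — a unit-norm smoothed Gaussian random field (the diffuse aging
  pattern); `a_age` is its amplitude in intensity units per year
  (default 60);
* `η ~ N(0, aging_variability_sd²)` — an individual brain-age offset in
  years (default 5). This is the biological component of BAG variance;
  without it a well-fit age model has near-zero BAG spread and BAG AUC is
  driven entirely by residual matching noise, which is not the regime the
  brain-age literature describes;
* `P_dis` — the disease pattern, unit-norm, built as
  ρ·P_age + √(1−ρ²)·P_perp so its cosine overlap with the aging pattern is
  *exactly* `overlap_rho`. Its random field is smoothed at a finer spatial
  scale (`disease_pattern_scale`, default 3× finer), reflecting that AD
  atrophy is more focal than diffuse aging — and making it a pattern an
  untuned age model does not automatically encode;
* `s` — latent severity: 0 for CN; truncated-normal with means 2.0 (AD),
  1.5 (pMCI), 0.7 (sMCI). The severity distribution is a free design
  choice of this package (no published cohort reports one); the ordering
  pMCI > sMCI couples severity to progression risk;
* per-scanner additive offset (sd 3) and multiplicative gain (sd 0.05),
  drawn once per scanner — the simplest site-effect mechanism;
* `ε` — iid voxel noise (sd 4).

MCI diagnosis trajectories: the exposed primitive converts at each
follow-up visit with probability h = logistic(progression_hazard · s),
absorbing into AD. The cohort generator, which must hit requested
sMCI/pMCI counts exactly, samples progressors' conversion visits from that
hazard's geometric law truncated to the 36-month window and keeps stable
subjects MCI throughout; the unconditional primitive is what the
trajectory tests exercise.

Determinism: everything derives from `GeneratorConfig.seed` via
`SeedSequence`; per-subject streams are keyed by a CRC of the subject id,
so cohorts are bit-reproducible and individual volumes re-renderable in
isolation.

What the generator does **not** emulate: skulls, bias fields, motion,
registration error, nonlinear atrophy topography, longitudinal image
change (one scan per subject), or realistic covariance between regions.
Passing tests therefore demonstrate that the *pipeline machinery* (matching,
splits, training regimes, transfer, statistics) behaves correctly and that
the BAG-versus-direct mechanism responds to pattern overlap as theory
predicts — not that any particular real-data AUC would be reproduced.

## Preprocessing

Only the tail of the T1 pipeline is in scope: the fixed border crop
(default window [6:173, 2:214, 0:160], 0-based half-open, taking a
182×218×182 registered image to 167×212×160) and intensity normalization
to [0, 1] by dividing by 255. Skull-stripping, reorientation and linear
registration are external-tool stages; synthetic volumes are rendered
pre-registered, and real-data users must supply externally preprocessed
NIfTI.

## Matching, splits, subsampling

Matching is greedy, per scanner: members of the smaller diagnostic group
are processed in ascending age (ties by subject id) and paired without
replacement to the same-sex candidate with minimal |Δage| (ties by subject
id); excess majority members are excluded, and a minority member with no
same-sex candidate is dropped with a logged warning. Sex must match
exactly; age is matched as a continuous variable with no caliper. On the
documented toy example the greedy result coincides with the
enumeration-optimal assignment, which the test verifies by brute force.

Splits are nested 80:20 development:test then 80:20 train:validation,
stratified per scanner and class, repeated k times (k = 50 at full scale;
desk suites use k = 2–5). Stratum counts use half-up rounding
(test = round(0.2 n), validation = round(0.2 (n − test)), remainder train)
so split sizes are reproducible; a stratum under 5 participants triggers a
warning. Development subsampling draws size/2 per class, re-splits 80:20,
and never touches the test set, so AUCs are comparable across development
sizes.

## The SFCN and its training regimes

The backbone is the standard SFCN layout; the appended block is a 1×1×1
convolution, batch normalization and global average pooling; dropout sits
between pooling and the fully connected head. Convolutions carry biases
and batch normalization is affine — that combination reproduces the
reference parameter counts exactly (2,950,466 / 2,950,401 / 65). The
layer stack, backpropagation and SGD loop are implemented in numpy
(im2col convolutions; the input-adjacent convolution skips its unused
image gradient).

Reference training hyperparameters are the fixed set used for every model:
SGD, weight decay 1e-4, dropout 0.5, initial learning rate 0.1 (0.01 for
finetuning), ÷10 every 30 epochs, batch 6, 150 epochs, best-epoch
checkpoint selection on validation AUC (classification) or MAE
(regression) with ties to the earliest epoch — "early stopping" selects a
checkpoint, it never halts. Classification minimizes cross-entropy;
regression minimizes MAE, and a freshly initialized regression head starts
at the training-mean age so the L1 loss optimizes deviations rather than
the global offset.

Desk-scale presets (filters [8,16,16,8], 32×40×32 volumes, batch 8) keep
every code path CPU-feasible, with three deliberate adaptations:

* dropout 0.25 — dropping half of 8 features is far harsher than half of
  64, and 0.5 visibly starves desk-scale learning;
* pretraining at lr 0.03 for 30 epochs (decay at 20) — lr 0.1 oscillates
  under the L1 loss at this scale;
* finetuning at lr 0.1 with **frozen, pre-calibrated** batch-norm
  statistics (below) — the desk pretrained backbone is weak enough that
  the conservative reference finetuning rate cannot re-adapt it.

### Batch normalization under transfer

The discriminative direction the logistic stage finds lives in a
near-null-space of the strongly correlated pooled features (its logit
scale is ~2 orders below the feature common mode). Running-statistic
updates with momentum 0.1 from batch-8 statistics perturb features by more
than that entire signal, which inverts the transferred rule within one
epoch. The feature-using approaches therefore first *calibrate* the
running statistics on the development set (equal-weight batches, no weight
updates) and the desk finetune presets keep them fixed during training
(`TrainConfig.update_bn_stats = False`). At reference scale the default
remains the standard updating behaviour.

### Brainage64D-finetune head

The trained logistic stage (65 parameters on raw features, after folding
out the z-scoring) is unfolded into an antisymmetric 2-output fully
connected head — giving the finetuned model the same trainable-parameter
count as the direct classifier — and normalized to unit weight norm before
end-to-end cross-entropy finetuning. The normalization is a softmax
temperature choice; it preserves the decision rule exactly and keeps
initial logits in a trainable range.

## Approaches

* **direct** — SFCN 2-class from scratch per repetition.
* **bag** — BAG of the pretrained regression model thresholded over all
  cutoffs; implemented as the rank AUC of the BAG scores, which is
  mathematically the same statistic. The development set is untouched.
* **bag_finetune** — all weights finetuned to predict age on the CN half
  of the development set (MAE loss, epoch selected by CN validation MAE),
  then BAG on the test set.
* **brainage64d** — logistic ridge on the pooled features; the inverse
  regularization λ ∈ {0.001, …, 1000} is selected by validation AUC (ties
  to the smallest λ, i.e. strongest penalty) and the model is refit on the
  full development set at the chosen λ. Features are z-scored with the
  statistics of the set being fit, for penalty comparability.
* **brainage64d_finetune** — the Brainage64D model finetuned end to end,
  epoch selected by validation AUC.
* MCI: **direct**, and the two **AD2prog** transfers, which extract pooled
  features from the frozen AD model of the same repetition (trained at the
  full AD sample size, also for learning-curve runs) and fit the logistic
  ridge stage.

A leakage audit (`audit_leakage`) checks per approach and repetition that
no test subject appears in any training, validation or finetuning stage;
it runs as a test over all produced results.

## Statistics

AUC is pairwise concordance with half credit for ties (delegated to
scikit-learn, verified against a brute-force oracle). The corrected
resampled t-test uses d̄ / √((1/k + n₂/n₁) s_d²) with k−1 degrees of
freedom, n₁ = development size and n₂ = test size — the resampling unit is
the whole development set, redrawn each repetition. Identical series
return (t = 0, p = 1) by convention. Benjamini–Hochberg runs at q = 0.05
over all pairwise comparisons within one results table. Matching balance
is a paired t-test on within-pair age differences and a chi-square
goodness-of-fit of one group's sex counts against the other's. Box
summaries use linear-interpolation quartiles and 1.5·IQR whiskers.

## Mechanism-recovery study conditions

The acceptance suite fixes one synthetic world (seed 11; two scanners;
24 CN + 24 AD per scanner; ages 55–90; a_age = 60, η sd = 5 y, noise 4,
site 3/0.05) and a healthy 128-subject pretraining cohort from a separate
"dataset" of the same world (the age model must not see evaluation
subjects). Two regimes differ only in the disease pattern:

* **orthogonal** (ρ = 0, a_dis = 120): BAG carries no disease information —
  its mean AUC over 5 repetitions must sit in the null band 0.5 ± 0.13
  (test-set concordance noise plus the cohort-level imbalance of latent
  aging offsets between matched groups) — while the direct classifier
  exceeds 0.8. The same regime is the misaligned-signal setting for the
  ordering BAG < Brainage64D < {Brainage64D-finetune, Direct}, each step a
  one-sided corrected t-test at 5%.
* **aligned** (ρ = 1, a_dis = 450, i.e. disease ≡ 15 equivalent years):
  BAG exceeds 0.8 and agrees with the two-Gaussian closed form
  Φ((μ₁−μ₀)/√(σ₀²+σ₁²)) computed from the per-repetition BAG moments.

The desk amplitudes are larger than a literal voxel-for-voxel scaling of
real effect sizes because a 32×40×32 volume pools ~140× fewer voxels than
a full-resolution scan; amplitudes were chosen so that pooled
signal-to-noise, not per-voxel contrast, is in a realistic regime. These
conditions (and the problem sizes above) are the package's fixed study
conditions; the full suite runs in roughly 11 minutes on one CPU.

## Degenerate inputs and conventions

Empty visit lists, single-class training sets, windows larger than the
volume, oversized subsampling requests and malformed configs raise typed
errors naming the offending field. Odd subsample sizes fall back to
size − 1 with a warning. Zero-variance AUC differences give t = 0, p = 1.
Max pooling truncates trailing odd voxels (floor division per axis).
Learning-rate epochs are 0-based: epochs 0–29 run at the initial rate.

## Known limitations

The generator's single-pattern disease model cannot express heterogeneous
atrophy subtypes; site effects are global per scanner rather than
spatially structured; severity is independent of age. The numpy training
loop is single-threaded BLAS-bound and intended for desk-scale volumes —
at full 167×212×160 scale it computes correct forward passes and exact
parameter counts, but training there is not its purpose. The corrected
resampled t-test is known to be conservative; the type-I test asserts only
the absence of gross anti-conservatism.
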