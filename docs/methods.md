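# Methods

## Model

`morphomil` treats a slide as a bag of patch instances with a single
binary label (death within 60 months). Each patch carries two embeddings:
a generic vector `g ∈ R^{d_g}` from an arbitrary pluggable encoder and a
morphology-informed vector `m ∈ R^{d_m}` taken from the post-ReLU 512-unit
hidden layer of a 13-class tissue-type classifier. Both streams are
linearly projected to a common width `p` (the real streams have unequal
dimensions, so a shared projection space is required before any bilinear
combination), and their outer product forms the per-patch cross-feature
interaction `f' = m' g'ᵀ ∈ R^{p×p}`. A learned map `T` — row-major
flatten, affine, rectifier — compresses `f'` to the fused patch feature
`f ∈ R^{d_out}`, with `d_out ≤ p²` so `T` is a genuine compression. Gated
attention (a tanh branch elementwise-multiplied by a sigmoid gate, scored
linearly and softmax-normalized across patches) weighs the fused features;
the attended sum is the slide embedding, and a logistic head maps it to
risk. Attention weights are nonnegative and sum to one, and the whole
forward pass is permutation-invariant in patch order (equivariant for the
weights) — both properties are tested.

Interpretation note: the compression `T` is trained end-to-end under the
survival loss only. Retaining the information in `f'` that is useful for
outcome prediction is the operational reading of an
information-preservation motivation; no explicit mutual-information
estimator is involved.

## Training

Binary cross-entropy (predictions clipped to `[1e-7, 1-1e-7]`) plus an L1
penalty on every linear weight matrix (biases excluded), coefficient
5×10⁻⁴; Adam at learning rate 2×10⁻⁵; batch size 1 (one slide per step);
Xavier-uniform initialization for all tensors except the attention score
vector, which starts at zero so pooling is uniform at step 0 and the
attention polarity is learned from data rather than inherited from the
random draw; no dropout (the L1 term provides the regularization).
Gradients are derived by hand and checked against central finite
differences; a global-norm clip at 5 guards batch-size-1 spikes.

The epoch budget is the package's own choice: up to 60 epochs with
early stopping after 10 epochs without validation-AUC improvement, and the
returned model is the snapshot of the best validation epoch. When the
validation AUC is undefined (single-class validation draw), training loss
substitutes as the selection signal. Two runs with identical data, config
and seed produce bit-identical histories.

Slides are keyed individually; when a patient contributes several slides,
patient-level risk is the mean of slide-level risks (the cohort this
emulates has 431 slides for 424 patients and no stated merging rule).

## Stratified cross-validation

Covariates are binned — age <65 vs ≥65 years; BMI <25, 25–30, ≥30 kg/m²
(boundaries to the upper bin; a "gapped" variant with cutpoints 24/30 is
selectable because the two published descriptions of the scheme disagree,
and the contiguous reading is the default); median household income cut at
$43,194; sex as recorded. K-modes (Huang style: modes initialized by
seeded farthest-point selection over the distinct rows — far more reliable
than a uniform draw at reaching the planted optimum — matching
dissimilarity, majority-category mode updates, best of 10 restarts)
clusters the bin vectors; K comes from the
elbow rule — the point of the cost curve farthest from the chord joining
its endpoints, ties to smaller K. Within each cluster, patients are dealt
round-robin (seeded shuffle, rolling offset) into five test folds, which
therefore partition the cohort with per-cluster composition within one
patient of proportionality. Per fold, 10 % of the *total* cohort is drawn
cluster-proportionally (largest-remainder quotas) from the non-test pool
as validation; the literal wording "10 % of the total cases" is read as
total cohort size, not 10 % of the remaining 80 %. Outcome labels never
enter clustering or splitting.

## Evaluation

Classification threshold = Youden's J maximizer over midpoints of sorted
unique validation scores (lower threshold on ties; 0.5 fallback with a
warning when validation is degenerate). AUC is the Mann–Whitney
probability with ties counted ½. The concordance index counts comparable
pairs (event before event, or event before censoring). Hazard ratios come
from a Cox partial likelihood with Efron tie handling, 95 % CI from the
observed information; risk groups for HR/KM analyses are a median split
of the pooled test risk scores (the source protocol does not state its cut
rule). Kaplan–Meier curves use the product-limit estimator and groups are
compared with the 1-df log-rank test. Paired model comparison applies the
two-sided Wilcoxon signed-rank test to per-patient Brier scores, dropping
zero differences; the exact null distribution is used for small samples
and the tie-corrected normal approximation otherwise. Undefined metrics
(single-class labels, empty denominators, no comparable pairs) are flagged
or raised, never silently reported as 0.

Cox/KM/log-rank/c-index computations are delegated to `lifelines` and AUC
to `scikit-learn`; the test suite cross-checks them against naive
enumeration oracles, and the model core is never delegated.

## Synthetic cohort generator

The generator emulates the *shape* of a WSI survival study so the entire
pipeline can be exercised without restricted data. Per patient: a
covariate profile drawn from six planted bin templates (numeric values
uniform within the bin, 2 % per-covariate chance of an off-profile bin); a
13-class morphology composition; patch class labels from the composition
with class-conditional Gaussian embeddings in both feature spaces
(unit-direction centers scaled to 3, correlation 0.7 between the spaces,
unit noise); and an exponential survival time with log-hazard
`η = β_signal (π_risk − E π_risk) + β_covᵀ x`. The linear predictor is
centered so `baseline_hazard` (0.012/month) is the hazard of a
cohort-average slide; with `β_signal = 0` the cohort reduces exactly to
that baseline, which keeps the null-control prevalence near one half.
Censoring is uniform on (0, 120) months at rate 0.2; the binary label is
death before 60 months, patients censored alive before 60 months are
excluded from the binary cohort (mirroring the study's exclusion of
cases censored within five years) but kept in the latent truth record.

The risk-class share `π_risk` follows a near-bimodal symmetric
Beta(0.036, 0.036) by default (a three-component mixture with near-pure
and risk-free slide archetypes is available through the config); the
remaining share is split over the twelve background classes with a
Dirichlet(0.3), so each slide has a diverse non-tumor background.
Defaults: 300 patients, 30–60 patches per bag, `d_g = d_m = 32`,
`β_signal = 3`, risk class = high-grade adenocarcinoma (class 0).
Deliberate design points:

- **Near-bimodal risk share.** Under an exponential hazard with the
  effect size fixed at 3 over a [0, 1] class fraction, the Bernoulli
  ceiling on bag-level AUC is ≈0.90 no matter how informative the
  features are; it is approached only when the risk-class share has high
  variance and the horizon hazard of a risk-free slide sits near 0.2.
  The sparse Beta realizes exactly that — most slides are either
  dominated by or essentially free of the high-grade class, the
  realistic regime for resection slides — so a correctly implemented
  model has headroom to demonstrate recovery. A bag-mean
  logistic-regression oracle reaches ≈0.89 under these defaults, and the
  trained pipeline's pooled AUC varies roughly 0.86–0.92 with the cohort
  draw.
- **What the generic stream lacks.** The two streams are deliberately
  asymmetric, reflecting why a morphology-informed stream helps at all:
  the generic encoder's class centers coincide for the two
  adenocarcinoma grades and the two adenoma grades (a generic encoder
  sees "adenocarcinoma", not the grade the hazard depends on), its
  patch noise is higher (1.2 vs 1.0), and every slide's generic
  embeddings share a random per-slide offset (sd 0.7 per component)
  emulating stain/scanner batch effects that self-supervised encoders
  are known to carry and that patch averaging cannot remove. The
  morphology stream — trained on the target domain — is modeled as free
  of these. This is what gives the morphology-ablation comparison its
  information gap, rather than an accident of optimization. An optional
  `severity_gradient` additionally shifts risk-patch morphology
  embeddings along a fixed direction with the slide's tumor share
  (within-class phenotypic gradation); it is off by default.
- **Planted profile geometry.** The six covariate templates are the
  6-subset of the 24 possible bin combinations whose ideal K-modes cost
  curve drops near-linearly to a flat tail at K = 6, which makes the
  chord-rule elbow well defined (no 6-subset with pairwise Hamming
  distance ≥3 exists in this bin space). The small off-profile noise
  keeps the post-6 tail realistic without eroding the knee.

What the generator does **not** emulate: real pixel statistics, spatial
autocorrelation of patch classes within a slide, site/scanner effects,
non-proportional hazards, informative censoring, or any treatment-arm
biology (a treatment column is generated independent of outcome, matching
the null treatment effect in the source trial). Passing tests therefore
show correctness of the machinery and recoverability of a planted
composition signal — not clinical performance on real cohorts.

### Attention polarity under a graded composition signal

A point worth stating explicitly, because it constrains what attention
maps can show on data of this kind. When the slide label is driven by the
*fraction* of a morphology class and positive slides are dominated by
that class — which is exactly the regime a strong composition signal
forces under a proportional-hazards link with a bounded effect size — the
attention weights of a mean-pooled MIL model carry no intrinsic
preference for the risk-class patches: amplifying the minority background
patches discriminates compositions just as well, and the mislabeled bags
in every graded region push the learned scores toward that background
polarity. Instrumented training runs confirm the net score gradient on
risk-class patches stays adverse across seeds and across many generator
variants. By contrast, when the outcome depends on the *presence* of a
sparse informative class (the classic MIL regime), the identical
architecture and optimizer concentrate attention on precisely those
patches in essentially every positive bag. The training suite therefore
demonstrates localization in the presence-label regime; on the graded
reference cohort the sign of the learned polarity depends on the cohort
draw (roughly half of seeds localize positively under the final design),
and the end-to-end suite retains the check as an honest record of that
limit (its p-value is also reported by the reproduction script alongside
the presence-regime control). On real slides, which regime dominates is
an empirical question; interpretation of attention maps should be
validated against expert annotation rather than assumed.

## Problem sizes and numerics

Tests and the acceptance script run a desk-scale model (`p = 16`,
`d_out = 32`, attention width 32) on the 300-patient cohort; the
`FusionConfig` defaults (`p = 64`, `d_out = 256`, width 128) are sized for
real embedding dimensions. Softmax and sigmoid use max-subtraction /
`expit` for stability; K-modes ties break toward the smallest category
code and lowest cluster index, making every clustering deterministic under
its seed. Bag files store features as float32 and labels as 8-bit
integers; model math runs in float64.

## Known limitations

- The attention-localization check uses the generator's latent patch
  classes; on real data it would require expert annotation of
  high-attention regions.
- The Wilcoxon comparison assumes paired predictions on identical
  patients; cross-cohort comparison is out of scope.
- Exact reproducibility is guaranteed per platform/BLAS build;
  cross-platform bit-identity of floating-point reductions is not.
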