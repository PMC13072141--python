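# morphomil

Morphology-aware multiple-instance survival prediction for whole-slide-image
feature bags.

## The problem

Five-year overall survival in resected colorectal cancer is hard to predict
from routine H&E slides: the prognostic signal is spread across
heterogeneous tissue morphologies (high-grade carcinoma, stroma, necrosis,
mucin, ...) that generic self-supervised patch embeddings capture only
implicitly. `morphomil` implements a feature-level pipeline that fuses two
embedding streams per 224×224 patch — a *generic* stream from any
foundation-model encoder and a *morphology-informed* stream from a 13-class
tissue-type classifier head — and aggregates them into a slide-level
survival probability with gated attention.

For a slide with patches \(j = 1..m\), the model computes

```
g'_j = Wg g_j,   m'_j = Wm m_j                  (projections to R^p)
f'_j = m'_j g'_jᵀ                               (cross-feature interaction, p×p)
f_j  = ReLU(T vec(f'_j))                        (learned compression to R^d)
a_j  = softmax_j( wᵀ(tanh(Vᵀf_j) ⊙ σ(Uᵀf_j)) )  (gated attention)
Z    = Σ_j a_j f_j,     risk = σ(w_outᵀ Z + b)  (slide embedding → 5-year risk)
```

trained end-to-end with binary cross-entropy, Adam (lr 2×10⁻⁵, batch size
1), Xavier-uniform initialization and an L1 penalty (5×10⁻⁴) on all linear
weights. The positive label means death within 60 months of treatment
initiation.

Around the model core the package provides:

- **Tiling** (`morphomil.tiling`): non-overlapping 224-px grids with an
  HSV tissue filter (patches with <25 % tissue are excluded).
- **Morphology head** (`morphomil.morphology`): the input→512→128→13 MLP
  whose post-ReLU 512-unit layer is the morphology feature extractor.
- **Stratified splits** (`morphomil.splits`): covariate binning (age 65,
  BMI 25/30, income $43,194, sex), K-modes clustering with elbow-selected
  K, and cluster-balanced five-fold construction with a 10 % validation
  carve-out.
- **Evaluation** (`morphomil.evaluation`): AUC, Youden-threshold
  classification metrics, concordance index, Cox hazard ratios (Efron
  ties), Kaplan–Meier curves with the log-rank test, and paired model
  comparison by Wilcoxon signed-rank on sample-wise Brier scores.
- **Synthetic cohorts** (`morphomil.synthetic`): a generator with planted
  morphology-composition signal, covariate profiles and exponential
  survival, so the whole pipeline is testable without any restricted data.

## Worked example

```python
from morphomil import SimConfig, TrainConfig, generate_cohort, cross_validate
from morphomil.fusion import FusionConfig
from morphomil.splits import bin_covariates, build_folds

bags, cohort, truth = generate_cohort(SimConfig(seed=0))   # 300 patients
folds = build_folds(bin_covariates(cohort), K=6, seed=0)
result = cross_validate(
    bags, folds, TrainConfig(seed=0),
    FusionConfig(d_g=32, d_m=32, p=16, d_out=32, l=32, seed=0),
)
print(f"pooled held-out AUC: {result['pooled_auc']:.3f}")
print(result["fold_metrics"][["auc", "accuracy"]].round(3))
```

prints

```
pooled held-out AUC: 0.858
     auc  accuracy
0  0.820     0.850
1  0.788     0.783
2  0.898     0.833
3  0.846     0.817
4  0.948     0.883
```

i.e. five-fold training recovers the planted composition signal (the true
log-hazard carries a Bernoulli ceiling of about 0.90 under this
generator; pooled AUC varies roughly 0.86–0.92 with the cohort draw), and
the per-fold thresholded accuracies come from thresholds chosen on each
fold's validation set.

A thin CLI mirrors the stages: `morphomil simulate|split|train|evaluate|tile`
(see `--help` on each subcommand).

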