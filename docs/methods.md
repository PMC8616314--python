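# Methods

## The discrimination problem

Glioblastoma multiforme (GBM) and solitary brain metastasis (SBM) present
similarly on conventional MRI; quantitative radiomics features extracted
from tumour sub-volumes on several MR sequences can separate them, but a
single sequence captures only part of the available contrast. The package
implements a two-level fusion pipeline: per-feature fusion of the
cross-sequence information using the class structure of the training
cohort, followed by an accuracy-weighted consensus over the
best-performing classification models. The positive class is GBM (label
1) throughout; sensitivity is the positive-class recall.

## Feature-level fusion

For feature j, let X ∈ ℝ^{p×n} hold its standardized values on the p
sequences (rows) over the n training samples (columns). The between-class
scatter is

S = Σᵢ nᵢ (x̄ᵢ − x̄)(x̄ᵢ − x̄)ᵀ,

summed over the two classes with class means x̄ᵢ, class sizes nᵢ and grand
mean x̄. For c = 2 classes S has rank ≤ 1; in fact S = (n₁n₀/n) d dᵀ with
d = x̄₁ − x̄₀, which gives the closed-form eigenpair λ = (n₁n₀/n)|d|²,
q = d/|d| used as the independent oracle in the tests.

"Unitization" is implemented as eigen-whitening: eigendecompose
S = QΛQᵀ, retain eigenpairs with λ > tol·λ_max (tol = 1e−10), and set
W = Q_r Λ_r^(−1/2), so that WᵀSW = I_r. With two classes r = 1 and WᵀX is
the fused 1×n row of feature j; the m rows stack into F ∈ ℝ^{m×n}. The
projection maximizes class-mean separation relative to the scatter scale
in the direction of d, which is why the fused feature concentrates the
complementary class information of the p sequences into one value.

Numerical conventions:

- **Standardization.** Features are z-scored per (modality, feature) with
  statistics from the training samples only. Scatter-based fusion is
  scale-sensitive across modalities, so standardization makes the
  transform well-posed; the statistics are stored inside the
  `FusionTransform` and reused verbatim at test time, so applying the
  transform involves no fitting whatsoever.
- **Sign.** Eigenvectors are sign-ambiguous. Each W column is first
  oriented by making its largest-magnitude entry positive (determinism
  across eigensolvers), then flipped if necessary so the positive class
  has the larger fused mean — fused values are therefore comparable
  across features and runs.
- **Degenerate features.** If the between-class scatter is numerically
  zero (identical class means), no eigenpair survives; the feature falls
  back to the uniform average across modalities, W = (1/√p)·1, and is
  flagged rather than dropped, keeping F rectangular and aligned with the
  registry.
- **Zero-variance features** keep scale 1 in the standardizer (flagged)
  for the same alignment reason.

## Model-level fusion

Fifteen models — the Cartesian product of five feature selectors (ANOVA
F-score, mutual information, ReliefF, L1-regularized logistic ranking,
greedy mRMR) and three classifiers (logistic regression, RBF-kernel SVM,
random forest) — are each evaluated by stratified five-fold CV on the
fused training table. Feature selection is refit inside every fold, so
held-out folds never influence the selected features; when the CV wraps a
multi-modality bundle (the sequence sweep), the fusion transform itself is
also refit per fold on the training folds only. Each model keeps
`selector_k` = 10 features by default. ReliefF and mRMR are implemented
in-package (L1-distance ReliefF with 10 neighbours; mRMR as F-score
relevance minus mean absolute Pearson correlation to already-selected
features); the remaining selectors and all classifiers come from
scikit-learn.

Models are ranked by mean CV AUC (ties: mean accuracy, then model id);
the top 3 are refit on the full training cohort and combined with weights
wᵢ = accᵢ/Σₖ accₖ, where accᵢ is the model's mean CV accuracy. Member
outputs cᵢ(x) are class-1 probabilities (soft voting): a weighted sum of
hard labels would collapse to weighted voting and discard the resolution
of the accuracy weights. The consensus score Σ wᵢcᵢ(x) is convex in the
member scores; class 1 is predicted at score ≥ 0.5 (configurable). A
plurality majority-vote baseline over the same members is provided, with
ties broken toward the positive class (warned).

## VOI utilities

Delineations from two readers are reconciled by the Dice similarity
coefficient 2|A∩B|/(|A|+|B|): strictly above 0.9 the voxelwise
intersection becomes the consensus VOI; at or below it the pair is routed
back for review (the boundary case is deliberately *not* conformant).
Dice of two empty masks is defined as 1.0 with a warning. Morphological
union of the three base VOIs (nET, ET, pTE) yields the seven VOI types —
three singletons, three pairwise unions, the triple union — in that
canonical order. Masks are NIfTI; combining masks of different grid
shapes is an error, never an implicit resample.

## Synthetic data

The clinical cohort is not publicly deposited, so the generator stands in
for it. For sample with class y ∈ {0,1}, feature j, modality k:

value = δ_jk·y + ε, ε jointly normal across modalities with unit
variance and equicorrelation ρ (valid for ρ ≥ −1/(p−1)).

This Gaussian equal-variance model was chosen for its closed-form oracle:
a single feature with effect δ has AUC = Φ(δ/√2), which the tests verify
to within 0.02 at n = 5000/class. Complementarity mode places the
informative features of different modalities on disjoint sets (fusion
should help); shared mode with ρ → 1 makes modalities redundant (fusion
should not help materially) — both regimes are asserted.

The default study scenario mirrors the cohort shape of the motivating
study: 121 training samples (61 positive / 60 negative), 62 held-out
(33/29), four sequences named T1WI, CE_T1WI, T2WI, T2_FLAIR, and the
109-feature registry. T1WI and T2_FLAIR are strongly informative (δ = 0.8
on disjoint 33-feature blocks — moderate single-feature separation,
AUC ≈ 0.71, so that multivariate models reach realistically high but
imperfect performance); CE_T1WI and T2WI are weakly informative
(δ = 0.3 on 11 features each). What the generator does **not** emulate:
the heavy-tailed, highly inter-correlated covariance of real radiomics
features, batch effects across scanners, or any image-level structure —
passing tests demonstrate the correctness and calibration of the method's
mathematics and bookkeeping, not clinical performance.

## Study harnesses and statistics

AUC uses the rank (Mann–Whitney) formulation with ties credited 0.5
(scikit-learn implementation, verified in tests against a brute-force
all-pairs concordance count). Paired comparisons use the two-sided
Wilcoxon signed-rank test, dropping zero differences; an all-zero
difference vector is flagged degenerate. For the reader-comparison
harness the model-vs-reader comparison on a single test set uses paired
bootstrap resampling (2000 replicates by default, seeded) of per-replicate
accuracies feeding the Wilcoxon test. The top-feature analysis counts
feature selections across model-fold fits of models whose mean CV AUC
exceeds 0.8; the threshold analysis uses M = (mean₁ + mean₀)/2 per
feature, with values exactly at M counted as below.

The null-calibration study draws pure-noise tables (labels permuted
independently of features) at n = 500 with 20 features and 20 replicates
and checks the zoo's grand-mean CV AUC is 0.5 ± 0.05 — a direct test that
no information leaks through the fold structure. The feature count is
kept modest because the null property is dimension-free.

## Reproducibility

Every stochastic component draws from a single base seed through a
namespaced SHA-256 derivation (`utils.derive_seed`), so CV shuffles,
simulations, SVM probability calibration and forest bootstraps are
jointly reproducible; re-running any entry point with the same seed
reproduces all numeric outputs exactly.

## Known limitations

- The scatter construction assumes exactly two classes; the rank-1
  structure (and hence the 1×n fused row) would not hold for c > 2.
- SVM probabilities come from Platt scaling inside scikit-learn, which is
  itself cross-validated on the training folds; scores are calibrated
  only approximately.
- The reader-comparison bootstrap is a pragmatic substitution for a
  formal paired test of dependent ROC curves (e.g. DeLong); it compares
  accuracies, not AUCs.
- The generator's independence across features understates the multiple
  testing burden a real radiomics panel would present to the selectors.
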