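# Methods

## Problem and model

`pathblend` integrates several omics abundance matrices (e.g. metabolomics,
proteomics, transcriptomics measured on the same individuals) with a binary or
continuous outcome by working at the level of biological pathways instead of
individual molecules. The pipeline has three stages:

1. **Single-sample pathway analysis (ssPA).** Each standardized
   samples-by-molecules matrix is reduced to a samples-by-pathway activity
   matrix `A`. For pathway `p_i` with `L_i` covered members, the member
   columns are collected into `Z_i` (N x L_i) and summarised by either

   - `svd` (PLAGE-style): the top principal-component score of the
     column-centered `Z_i`, i.e. the projection onto the first right-singular
     direction, or
   - `kpca`: the first principal-component score of kernel PCA with an RBF
     kernel on `Z_i`.

2. **Supervised modelling.**
   - *Multi-view*: one pathway-score block per omics, fitted by multi-block
     PLS (NIPALS). Per latent variable r, unit-norm block weights `w_{k,r}`
     give block scores `t_{k,r} = X_k w_{k,r}`; unit-norm superweights
     `a_r` combine them into the superscore `t_{S,r}`; both the `X_k` blocks
     and `Y` are deflated by the superscore (Westerhuis-style), so
     superscores are mutually orthogonal. Prediction is `Y = X β + ȳ` with
     `β = W*(P'W)⁻¹C` on the concatenated, training-scaled features.
   - *Single-view*: blocks are standardized, column-concatenated, ssPA is
     fitted on the concatenation (pathways may mix omics members), and any
     predictor satisfying a `fit / predict_score / feature_importance`
     contract is trained on `A` (built-ins: PLS, random forest, logistic
     regression).

3. **Importance and significance.** Feature importance is variable importance
   in projection, computed from the deflated-matrix weights:
   `VIP_j = sqrt(J Σ_r w_rj² SSY_r / SSY_cum)` for one block and
   `MB-VIP_j = sqrt(f Σ_r w_krj² SSY_r / SSY_cum)` for k blocks, where
   `SSY_r` is the Y sum of squares removed by latent variable r and `f`
   the total feature count. Under unit-norm-per-block weights these satisfy
   `mean(VIP²) = 1` and `SS(MB-VIP)/(f·k) = 1`, which the tests assert on
   every fitted model. Significance comes from label-permutation empirical
   p-values (`p = #(permuted ≥ observed)/n_perm`, default 10,000 shuffles,
   resolution 1e-4) with Benjamini-Hochberg FDR across pathways.

## Semi-synthetic benchmark

A realisation shuffles the outcome labels (removing any real association
while preserving molecular covariance) and adds a constant `α` (a log2 fold
change) to every covered member of one target pathway in the new case group
only. Detection of the target among all pathways and case/control
classification then have exact ground truth. Detection is scored by the
confusion matrix at adjusted p ≤ 0.05 and by a rank-based AUC with mid-rank
tie handling (permutation p-values tie heavily on the 1/n_perm grid).

The univariate power experiment compares two detection routes per
realisation: (i) pathway-level — Mann-Whitney U on the target's ssPA scores,
Bonferroni over all scoreable pathways; (ii) molecular-level — MWU per
covered member, Bonferroni over the members, then a conditional Fisher
combination: if at least 50% of members are significant (gate evaluated on
adjusted p by default; a switch allows raw p), all member p-values are
combined by `-2Σln p ~ χ²(2m)`, otherwise the combined p is set to 1
exactly.

## Synthetic base generator

Real cohort matrices cannot be shipped, so a generator emulates their
structure: per pathway one latent Gaussian factor per block; member
molecules load on their pathway factor with `sqrt(ρ)` so the within-pathway
correlation is exactly `ρ`; block-level factors can share a common component
(cross-block correlation, default 0, mirroring a design with no enforced
between-omics correlation). Pathways additionally annotate a fraction
(default 10%) of molecules owned by other pathways, giving overlapping sets
without changing the covariance. Defaults — 200 samples, 2 blocks, 100
pathways of 4–12 molecules, ρ = 0.5 — are the package's study conditions,
sized so every experiment runs on a laptop in minutes.

What the generator does **not** emulate: heavy-tailed or skewed abundance
distributions, batch effects, missing-not-at-random patterns, realistic
pathway-size distributions (Reactome sizes are roughly log-normal with a
long tail), or cross-pathway correlation beyond annotation overlap. Passing
tests therefore demonstrate correctness and calibration of the machinery,
not expected power on any particular real cohort.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| `min_coverage` | 2 | molecules a pathway must have measured to be scored; simulation targets require ≥ 3 |
| ssPA `gamma` | `1/L_i` | RBF width per pathway; scale-free in pathway size |
| MB-PLS `R` | task-specific | chosen by nested CV; `tol` 1e-10 on superscore change, `max_iter` 500 |
| `n_perm` | 10,000 | p-value resolution 1e-4; p = 0 reported values mean p < 1/n_perm |
| bootstrap `n_boot` | 200 (loadings), 100 (block importances) | mean/sd resp. mean/SEM reported |
| correlation screen | \|rho\| ≥ 0.3, Bonferroni p ≤ 0.05 | superscore-vs-metadata filter |
| random forest | 200 trees, depth 10, min leaf 4, sqrt features, OOB | single-view default when chosen |
| imputation | rank min(10, N−1, M−1), tol 1e-5 | iterative SVD on log2 data, before standardization |
| CV | 5 folds x 5 repeats, stratified | AUROC on continuous scores; 95% normal CI over fold scores |

## Numerical choices

- Standardization uses the sample (n−1) standard deviation; zero-variance
  features are an error at fit time.
- ssPA directions are sign-fixed deterministically: loading sum positive,
  ties broken by making the largest-magnitude loading positive. Latent
  variables are sign-fixed by forcing the largest-magnitude superweight
  entry positive. Refitting identical data reproduces identical signs.
- A constant (zero-variance) pathway submatrix yields all-zero scores with a
  warning rather than an error, keeping matrix shapes stable under
  degenerate simulation inputs.
- Within each `Z_i`, columns are centered with training-set means even
  though globally standardized training data is already near-centered; this
  makes fit/transform exact on the training set.
- `SSY_r` is computed as the drop in the deflated Y sum of squares at step
  r, which makes the VIP normalization identities exact.
- Binary outcomes are encoded {0,1} and mean-centered; class calls use a
  0.5 threshold on the encoded scale; AUROC always uses the continuous
  score.
- Empirical p-values use the plain count/n rule with no +1 correction,
  permitting p = 0 (read as < 1/n_perm); permutations are full shuffles
  without excluding the identity; each permutation draws from an
  independent child stream of the master seed, so results do not depend on
  execution order.
- Nested LV selection evaluates each candidate R as a prefix of a single
  model fitted at max(R): NIPALS is sequential, so the first R latent
  variables coincide with a model fitted at the smaller R (asserted in
  tests). The inner 5-fold split is repeated 5 times and the smallest R
  within one standard error of the best mean inner AUC is selected; with
  a weak spike this selection is inherently noisy, which is why the
  benchmark reports a majority over seeds (ties toward the smaller R).
- Leakage control in cross-validation: standardizers and ssPA transformers
  are fitted per training fold only. Missing values are imputed once,
  upfront, on the full matrix (the iterative SVD imputer is transductive);
  datasets with missingness therefore carry a mild transductive step that
  the fold-wise guarantee does not cover.
- Ward/euclidean hierarchical clustering, Mann-Whitney U (exact for small
  tie-free groups, tie-corrected normal approximation otherwise), Spearman
  correlation and BH-FDR are delegated to scipy/statsmodels.

## Known limitations

- Only a single outcome column is exercised (the multi-block machinery is
  written for univariate Y).
- kPCA scores carry no per-molecule loadings; molecule-level attribution
  requires the `svd` method.
- The network export replaces an interactive explorer with static node/edge
  tables and GraphML.
- Acceptance-style experiment sizes (200 samples, 100 pathways, 100–200
  realisations) are chosen for desk-scale runtimes; power estimates at
  these sizes carry Monte-Carlo error of a few percentage points.
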