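# Methods

## Problem setting

Binary (or multi-class) classification of `N` samples by `M` features with
`M ≫ N`, where most features are noise. The canonical instance is a
genome-wide case-control study: `X[i, j] ∈ {0, 1, 2}` is sample `i`'s minor
allele dosage at SNP `j`, and `y_i ∈ {case, control}`. A continuous variant
(expression matrices) is handled by the same pipeline.

With uniformly drawn node subspaces of size `mtry`, the probability that a
node of a random forest sees any of `m` informative features is roughly
`1 − (1 − m/M)^mtry`, which is tiny when `m/M ~ 10⁻⁴`. Trees built from noise
splits are weak, and Breiman's bound on the generalization error,
`ρ̄ / s²` (mean tree correlation over squared strength), blows up as the
strength `s` collapses. The method below restores strength by screening
features first and forcing informative features into every node's subspace.

## Model

### Stage 1: shadow-feature importance screen

1. Build the extended matrix `X' = [X, X*] ∈ R^{N×2M}`: shadow column
   `M + j` is an independent uniform row permutation of column `j`
   (`numpy` `argsort` of i.i.d. uniforms), so it preserves the marginal
   distribution of feature `j` while destroying any association with `y`.
2. Grow a forest of `K_screen` CART trees on `X'` with uniform subspaces of
   size `mtry_screen` over the `2M` columns, and record every feature's Gini
   importance: the sum over that feature's split nodes of
   `(N(t)/N_root) · [Gini(t) − Gini_split(t)]`, averaged over trees.
3. Repeat `R` times with fresh permutations and fresh forests. Feature `j`
   collects importances `V_j = (v_{j1}, …, v_{jR})`; replicate `r`
   contributes the shadow ceiling `v*_r = max_{j} importance(shadow j, r)`.
4. Keep feature `j` when the one-sided Wilcoxon rank-sum test of
   `V_j > v*` has `p ≤ θ`. Comparing against the per-replicate *maximum*
   over all `M` shadows makes the reference the best score a provably null
   feature achieved anywhere in that replicate, which is what controls the
   passthrough of the other `M − m` null real features without an explicit
   multiple-testing correction; `θ` is a per-feature level against that
   extreme-value reference, not a family-wise error rate.

Survivors form the informative set `X̃`. If nothing survives,
`fit_tsrf` raises `NoInformativeFeaturesError` rather than fabricating a
model from noise.

### Stage 2: quality partition

Each survivor is tested for marginal association with `y` by Pearson's χ²
on the feature × class contingency table (no Yates correction). Genotypes
use their three dosage levels directly; continuous features are discretised
to tertiles for this test only. Features with `p ≤ α` form the strong group
`X_s`; the remainder form the weak group `X_w`.

### Forest with stratified subspaces

CART trees are grown on bootstrap samples of size `N` drawn with
replacement. At every node, the candidate subspace of size `mtry` is drawn
without replacement, stratified:

- `mtry_s = max(1, ⌊mtry · |X_s| / |X̃|⌋)` features from `X_s`,
- `mtry_w = mtry − mtry_s` from `X_w`,

with each quota capped at its group size and, when one group is exhausted,
reassigned to the other. The best split minimises
`Gini_split = (N_L/N) Gini(t_L) + (N_R/N) Gini(t_R)` over midpoint
thresholds of each candidate's distinct values; `x ≤ threshold` routes left.
Nodes are split until pure or below `n_min` samples. Class prediction is by
majority vote over trees (ties to the first class in sorted label order).

### Evaluation

- **Accuracy** counts a sample as correct only when its true class strictly
  out-votes every other class; vote ties are errors. Samples with zero
  voting trees (possible with `oob_only` votes) are excluded and logged.
- **AUC** is the rank-based Mann–Whitney statistic on the positive-class
  vote fraction, ties contributing ½.
- **OOB diagnostics**: margins `mr(x) = Q(x,y)/den − max_{j≠y} Q(x,j)/den`
  over out-of-bag votes; strength `s = mean(mr)`;
  `ρ̄ = var(mr) / (mean_k sd_k)²` with per-tree
  `sd_k = sqrt(p1_k + p2_k + (p1_k − p2_k)²)`, where `p1_k`/`p2_k` are tree
  `k`'s OOB fractions predicting the true class and the most-voted wrong
  class. The bound is `c/s² = ρ̄ / s²`, reported as NaN (with a warning)
  when `s ≤ 0`. The `+` sign inside `sd_k` follows the printed form of the
  estimator this implementation reproduces; the binomial variance identity
  would use `−`. The choice only rescales `ρ̄` and `c/s²` by a constant
  factor per forest and does not affect the between-model comparison made
  here, but the printed form is pinned so results are reproducible.
- **k-fold comparison**: stratified k-fold CV (scikit-learn
  `StratifiedKFold`, shuffled with the given seed). The *entire* pipeline —
  both screening stages — is refit inside every training fold, so no
  feature-selection information leaks into the test fold. The baseline is a
  plain forest built from the same tree code with uniform subspaces of the
  classic size `⌊log₂ M + 1⌋` over all `M` features.

## Parameters and defaults

| parameter | default | role |
|---|---|---|
| `R` | 30 | screen replicates; more replicates sharpen the Wilcoxon test (its smallest attainable p-value is ~`1/C(2R, R)`), at linear cost |
| `K_screen` | 50 | trees per screening forest; enough for stable mean importances at screening precision |
| `mtry_screen` | `0.1·M` | wide subspaces during screening so every feature is tried often enough to earn an importance |
| `θ` | 0.05 | stage-1 level against the shadow-maximum reference; `p ≤ θ` is kept (boundary retained) |
| `α` | 0.05 | stage-2 χ² level splitting strong from weak |
| `K` | 500 | trees in the final forest |
| `mtry` | `⌊√|X̃|⌋`, min 2 | subspace size over the screened set |
| `n_min` | 1 | grow to purity; bias is handled by aggregation, not pruning |

All randomness flows from a single integer seed. Each tree draws from its
own `numpy` `default_rng` stream keyed by `(seed, tree_index)`, so results
are independent of growth order and identical across machines; forests,
screens and CV folds are bit-reproducible.

## Synthetic data generator

`generate_case_control` draws dosages `Binomial(2, p)` — Hardy–Weinberg
genotypes at independent biallelic loci — with `p = control_maf`
everywhere except the planted SNPs in cases, where
`p = control_maf + effect_delta`. It emulates exactly the marginal
case-control association structure the screen is designed to detect, and
deliberately **does not** emulate linkage disequilibrium, epistasis,
covariates, population structure, missingness or genotyping error.
`generate_continuous` is the Gaussian analogue: standard-normal background
with a class mean shift of `effect_delta` SD on planted features.

## Numerical choices

- Split search is vectorised (per-candidate sort + cumulative one-hot
  counts); near-ties within `1e-12` of the best impurity are re-compared
  with exact integer fractions, and remaining ties break to the lower
  feature index, then lower threshold, so tree growth is deterministic.
- Recorded Gini decreases are clamped at 0 to absorb float round-off.
- Wilcoxon p-values use the exact null distribution when both samples have
  ≤ 12 observations and no ties, otherwise the normal approximation with
  continuity correction; an all-tied comparison returns p = 1.
- Forest/model JSON stores split thresholds as hex floats for bit-exact
  round-trips, plus a SHA-256 digest of the training matrix so `oob_only`
  voting refuses mismatched data.

## Limitations

- The screen tests marginal importance; purely epistatic features with no
  marginal effect can be removed in stage 1.
- χ² quality grading assumes enough samples per genotype × class cell to be
  approximately valid; very rare variants may be graded weak for lack of
  power rather than lack of effect.
- The stratified sampler guarantees at least one strong feature per node,
  which can overfit when the strong set is tiny and `N` is small; the OOB
  diagnostics make this visible but do not prevent it.
- Cross-validating the full pipeline is `k` times the cost of a single fit;
  the screen (R forests on a 2M-column matrix) dominates the runtime.
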