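# tsrf — two-stage quality-based random forests for case-control SNP data

`tsrf` classifies high-dimensional case-control data (genome-wide SNP
genotypes or expression matrices) and ranks the features driving the
prediction. In this regime the number of features *M* (10⁴–10⁶ SNPs) vastly
exceeds the number of samples *N* (hundreds), and only a small subset of
features carries signal. A plain random forest suffers here: a uniformly
drawn subspace of `mtry` features at each tree node almost never contains an
informative feature, so trees are weak and the forest's error bound degrades.

`tsrf` addresses this with a two-stage feature-quality screen run before the
forest is grown, then biases the per-node subspace draw toward the surviving
features.

## Algorithm

**Stage 1 — shadow-feature screen.** Extend the design matrix
`X (N × M)` to `X' = [X, X*] (N × 2M)`, where each shadow column of `X*` is
an independent row-permutation of the corresponding real column — same
marginal distribution, no association with the class label `y`. Grow a
forest on `X'` and record each feature's Gini importance (sum over nodes of
`(N(t)/N) · [Gini(t) − Gini_split(t)]`, averaged over trees). Repeat for
`R` replicates (fresh permutations each time), giving each real feature `j`
a sample of `R` importances `V_j = (v_j1 … v_jR)` and each replicate `r` a
shadow ceiling `v*_r = max_j importance(shadow_j, r)`. A feature is kept when
a one-sided Wilcoxon rank-sum test rejects `H0: median(V_j) ≤ median(v*)`
at level θ (default 0.05), i.e. its importance is systematically above
anything a null feature achieves. Survivors form the informative set `X̃`.

**Stage 2 — quality partition.** Each survivor is tested for marginal
association with `y` by a χ² test on the genotype × class contingency table
(continuous features are discretised to tertiles first). Features with
`p ≤ α` (default 0.05) form the *strong* group `X_s`, the rest the *weak*
group `X_w`.

**Forest with stratified subspaces.** CART trees (Gini split criterion,
midpoint thresholds, grown to purity by default) are built on bootstrap
samples, but each node's candidate subspace of size `mtry = ⌊√|X̃|⌋` is drawn
stratified: `mtry_s = max(1, ⌊mtry · |X_s| / |X̃|⌋)` features from the strong
group and `mtry_w = mtry − mtry_s` from the weak group. Every node therefore
sees at least one high-quality feature. Prediction is by majority vote;
a test sample is counted correct only when its true class strictly out-votes
every other class.

**Diagnostics.** Out-of-bag votes yield per-sample margins
`mr(x) = Q(x, y)/|K| − max_{j≠y} Q(x, j)/|K|`, the forest strength
`s = mean(mr)`, the mean tree correlation `ρ̄`, and the generalization-error
bound `c/s² = ρ̄/s²` — lower is better (strong, weakly correlated trees).

## Worked example

Simulate a cohort of 60 cases and 60 controls with 300 SNPs, of which 8 are
planted with a minor-allele-frequency shift of 0.3 in cases, then train and
inspect the model:

```bash
tsrf simulate --n-cases 60 --n-controls 60 --m-features 300 \
    --m-informative 8 --maf 0.2 --delta 0.3 --seed 7 --out cohort.tsv
tsrf train --input cohort.tsv --model model.json --report ranks.tsv \
    --trees 100 --replicates 10 --k-screen 50 --seed 7
```

```
wrote 120 x 300 dataset to cohort.tsv
trained on 120 samples: 7 informative features (7 strong / 0 weak), 100 trees -> model.json
```

The screen kept 7 of 300 SNPs. Rank the features (`removed` rows are shown
for context below the survivors):

```bash
tsrf rank --model model.json --top 5
```

```
rank	feature_id	group	importance	wilcoxon_p	chi2_p
1	snp_265	strong	0.01592329691459501	9.133589555477501e-05	4.7315259013435826e-08
2	snp_067	strong	0.015722769072160275	9.133589555477501e-05	2.0279286101236828e-07
3	snp_201	strong	0.012754804623442011	9.133589555477501e-05	6.033026494317367e-06
4	snp_276	strong	0.010691654931096011	0.00016491926038899677	3.01999986962182e-05
5	snp_183	strong	0.009047552209057489	0.005664848342237332	3.331430047316518e-05
```

Predict and cross-validate against a plain random forest baseline
(uniform subspaces of size ⌊log₂ M + 1⌋):

```bash
tsrf predict --model model.json --input cohort.tsv --output preds.tsv
tsrf evaluate --input cohort.tsv --folds 5 --trees 100 --replicates 10 \
    --k-screen 50 --seed 7 --out metrics.tsv
```

```
fold	model	accuracy	auc	strength	correlation	cs2
0	ts-RF	0.791667	0.864583	0.510683	0.261172	1.001437
0	RF	0.791667	0.854167	0.094184	0.042357	4.774981
...
mean	RF	0.733333	0.835417	0.087698	0.041079	5.882434
mean	ts-RF	0.775000	0.856250	0.507496	0.325367	1.528621
```

On this cohort the two-stage forest improves mean CV accuracy (0.775 vs
0.733) and dramatically lowers the error bound c/s² (1.53 vs 5.88) by
raising strength (0.51 vs 0.09).

## Library use

```python
from tsrf import SyntheticSpec, TsRFParams, fit_tsrf, generate_case_control, rank_features

truth = generate_case_control(SyntheticSpec(seed=7))
model = fit_tsrf(truth.dataset, TsRFParams(R=10, K_screen=50, K=100, seed=7))
print(rank_features(model, top_n=10))
```

See `docs/methods.md` for the model in full, parameter defaults and
numerical choices.
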