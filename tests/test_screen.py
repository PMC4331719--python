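from itertools import combinations
from math import comb

import numpy as np
import pytest

from tsrf import (
    ImportanceReplicates,
    ValidationError,
    chi2_association_pvalue,
    importance_replicates,
    make_shadow_extended,
    run_screen,
    stage1_filter,
    stage2_partition,
    stratified_subspace_sampler,
    subspace_sizes,
    wilcoxon_greater_pvalue,
)
from tsrf.screen import SHADOW_SUFFIX, draw_stratified_subspace


def enumeration_pvalue(x, y):
    """Full rank-assignment enumeration of P(W_x >= observed), no ties."""
    pooled = sorted(x) + sorted(y)
    pooled = sorted(set(pooled))
    assert len(pooled) == len(x) + len(y), "oracle requires tie-free samples"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank[v] for v in x)
    n, big_n = len(x), len(x) + len(y)
    hits = sum(
        1
        for c in combinations(range(1, big_n + 1), n)
        if sum(c) >= w_obs
    )
    return hits / comb(big_n, n)


# -- shadow extension ------------------------------------------------------


def test_shadow_shape_and_ids(separable_dataset):
    d = separable_dataset
    ext = make_shadow_extended(d, np.random.default_rng(0))
    assert ext.n_features == 2 * d.n_features
    assert ext.n_samples == d.n_samples
    assert ext.feature_ids[: d.n_features] == d.feature_ids
    assert all(f.endswith(SHADOW_SUFFIX) for f in ext.feature_ids[d.n_features:])
    assert ext.labels.tolist() == d.labels.tolist()


def test_shadow_columns_are_permutations(separable_dataset):
    d = separable_dataset
    ext = make_shadow_extended(d, np.random.default_rng(1))
    m = d.n_features
    for f in range(m):
        np.testing.assert_array_equal(
            np.sort(ext.values[:, m + f]), np.sort(d.values[:, f])
        )
    np.testing.assert_array_equal(ext.values[:, :m], d.values)


def test_shadow_deterministic(separable_dataset):
    d = separable_dataset
    a = make_shadow_extended(d, np.random.default_rng(7))
    b = make_shadow_extended(d, np.random.default_rng(7))
    np.testing.assert_array_equal(a.values, b.values)


# -- Wilcoxon screen -------------------------------------------------------


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([5, 6, 7], [1, 2, 3], 1 / 20),
        ([1, 4], [2, 3], 4 / 6),
        ([10, 20], [1, 2], 1 / 6),
    ],
)
def test_wilcoxon_exact_examples(x, y, expected):
    assert wilcoxon_greater_pvalue(x, y) == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(25))
def test_wilcoxon_matches_enumeration(seed):
    """Exact p-values equal the full enumeration oracle for |x|,|y| <= 6."""
    rng = np.random.default_rng(seed)
    nx = int(rng.integers(1, 7))
    ny = int(rng.integers(1, 7))
    vals = rng.permutation(100)[: nx + ny].astype(float)
    x, y = vals[:nx].tolist(), vals[nx:].tolist()
    assert wilcoxon_greater_pvalue(x, y) == pytest.approx(
        enumeration_pvalue(x, y)
    )


def test_wilcoxon_all_ties_is_one():
    assert wilcoxon_greater_pvalue([0.0, 0.0], [0.0, 0.0, 0.0]) == 1.0


def test_wilcoxon_empty_sample_rejected():
    with pytest.raises(ValidationError):
        wilcoxon_greater_pvalue([], [1.0])


# -- replicate importances / stage 1 ---------------------------------------


def test_importance_replicates_shapes(separable_dataset):
    rep = importance_replicates(separable_dataset, R=3, K_screen=5, seed=1)
    assert rep.real_scores.shape == (3, 5)
    assert rep.shadow_max.shape == (3,)
    assert (rep.real_scores >= 0).all() and (rep.shadow_max >= 0).all()


def test_importance_replicates_deterministic(separable_dataset):
    a = importance_replicates(separable_dataset, R=3, K_screen=5, seed=2)
    b = importance_replicates(separable_dataset, R=3, K_screen=5, seed=2)
    np.testing.assert_array_equal(a.real_scores, b.real_scores)
    np.testing.assert_array_equal(a.shadow_max, b.shadow_max)


def test_determining_feature_beats_shadow_max(small_signal_truth):
    """A feature that determines the label scores above the shadow maxima."""
    # keep it small: first 20 cases + first 20 controls (samples are ordered
    # cases first, so range(40) alone would be single-class)
    d = small_signal_truth.dataset.subset_samples(
        list(range(20)) + list(range(40, 60))
    )
    # force a deterministic relationship on feature 0
    vals = d.values.copy()
    vals[:, 0] = np.where(d.labels == "case", 2.0, 0.0)
    from tsrf import LabeledDataset

    d2 = LabeledDataset(vals, d.feature_ids, d.sample_ids, d.labels, "genotype")
    rep = importance_replicates(d2, R=5, K_screen=20, seed=3)
    assert rep.real_scores[:, 0].mean() > rep.shadow_max.mean()
    pvals, informative = stage1_filter(rep, theta=0.05)
    assert 0 in informative


def test_stage1_boundary_p_equal_theta_retained():
    rep = ImportanceReplicates(
        real_scores=np.array([[5.0], [6.0], [7.0]]),
        shadow_max=np.array([1.0, 2.0, 3.0]),
        R=3,
        K_screen=1,
        mtry_screen=1,
    )
    pvals, informative = stage1_filter(rep, theta=0.05)
    assert pvals[0] == pytest.approx(0.05)
    assert informative.tolist() == [0]  # p == theta is kept


# -- chi-squared association ------------------------------------------------


def test_chi2_perfect_association():
    stat, p = chi2_association_pvalue([0] * 10 + [1] * 10, ["a"] * 10 + ["b"] * 10)
    assert stat == pytest.approx(20.0)
    assert p < 1e-4


def test_chi2_exact_independence():
    stat, p = chi2_association_pvalue([0, 0, 1, 1] * 5, ["a", "b"] * 10)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_constant_feature():
    stat, p = chi2_association_pvalue([1, 1, 1, 1], ["a", "a", "b", "b"])
    assert (stat, p) == (0.0, 1.0)


@pytest.mark.parametrize("seed", range(20))
def test_chi2_matches_textbook_formula(seed):
    """Statistic equals sum (O-E)^2/E on random genotype x class tables."""
    rng = np.random.default_rng(seed)
    n = 60
    col = rng.integers(0, 3, size=n).astype(float)
    labels = rng.choice(["a", "b"], size=n)
    stat, _ = chi2_association_pvalue(col, labels)
    cats = np.unique(col)
    labs = np.unique(labels)
    table = np.array(
        [[np.sum((col == g) & (labels == l)) for l in labs] for g in cats],
        dtype=float,
    )
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if min(table.shape) < 2:
        assert stat == 0.0
        return
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())


def test_chi2_continuous_uses_tertiles():
    rng = np.random.default_rng(0)
    col = np.concatenate([rng.normal(0, 1, 60), rng.normal(2.5, 1, 60)])
    labels = ["a"] * 60 + ["b"] * 60
    stat, p = chi2_association_pvalue(col, labels, feature_kind="continuous")
    assert p < 1e-6  # strong separation survives discretisation


# -- stage 2 + sampler ------------------------------------------------------


def test_stage2_partition_invariants(small_signal_truth):
    d = small_signal_truth.dataset
    informative = np.arange(20)
    strong, weak, chi2_p = stage2_partition(d, informative, alpha=0.05)
    assert set(strong.tolist()) & set(weak.tolist()) == set()
    assert sorted(strong.tolist() + weak.tolist()) == informative.tolist()
    assert np.isnan(chi2_p[25])  # untested features stay NaN
    for f in strong:
        assert chi2_p[f] <= 0.05
    for f in weak:
        assert chi2_p[f] > 0.05


def test_stage2_empty_informative_rejected(small_signal_truth):
    with pytest.raises(ValidationError):
        stage2_partition(small_signal_truth.dataset, np.array([], dtype=int))


@pytest.mark.parametrize(
    "mtry, ns, nw, expected",
    [
        (10, 30, 70, (3, 7)),
        (5, 10, 0, (5, 0)),
        (5, 0, 10, (0, 5)),
        (2, 1, 99, (1, 1)),
        (10, 2, 2, (2, 2)),  # quotas capped at group sizes
    ],
)
def test_subspace_sizes(mtry, ns, nw, expected):
    assert subspace_sizes(mtry, ns, nw) == expected


def test_subspace_sizes_both_empty_rejected():
    with pytest.raises(ValidationError):
        subspace_sizes(5, 0, 0)


def test_sampler_exhaustive_strong_draw():
    strong = [3, 5, 9]
    sampler = stratified_subspace_sampler(strong, [0, 1, 2], 3, 2)
    rng = np.random.default_rng(0)
    for _ in range(20):
        out = sampler(rng)
        assert set(strong) <= set(out.tolist())
        assert out.size == 5


def test_sampler_always_contains_strong_feature():
    strong = [10, 11]
    weak = list(range(10))
    sampler = stratified_subspace_sampler(strong, weak, 1, 3)
    rng = np.random.default_rng(1)
    for _ in range(200):
        out = sampler(rng)
        assert set(out.tolist()) & set(strong)
        assert set(out.tolist()) <= set(strong) | set(weak)


def test_sampler_inclusion_frequency_hypergeometric():
    """Drawing 2 of 5 strong features: each appears with frequency 2/5."""
    strong = np.arange(5)
    rng = np.random.default_rng(42)
    hits = np.zeros(5)
    n_draws = 10_000
    for _ in range(n_draws):
        out = draw_stratified_subspace(strong, [], 2, 0, rng)
        hits[out] += 1
    freq = hits / n_draws
    assert np.all(np.abs(freq - 0.4) <= 0.02)


def test_sampler_size_exceeding_group_rejected():
    with pytest.raises(ValidationError):
        stratified_subspace_sampler([1, 2], [3], 3, 1)


def test_run_screen_bundles_consistent_result(small_signal_truth):
    d = small_signal_truth.dataset
    res = run_screen(d, R=8, K_screen=50, mtry_screen=12, theta=0.2, seed=4)
    assert res.wilcoxon_p.shape == (d.n_features,)
    np.testing.assert_array_equal(
        res.informative, np.flatnonzero(res.wilcoxon_p <= 0.2)
    )
    assert sorted(res.strong.tolist() + res.weak.tolist()) == res.informative.tolist()
    planted = set(small_signal_truth.informative_indices.tolist())
    assert planted <= set(res.informative.tolist())
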