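import math

import numpy as np
import pytest

from tsrf import (
    TsRFParams,
    ValidationError,
    binary_auc,
    baseline_mtry,
    fit_forest,
    forest_diagnostics,
    kfold_cv,
    margins,
    strength_correlation,
    uniform_sampler,
    votes,
)
from tsrf import test_accuracy as vote_margin_accuracy  # alias: not a test
from tsrf.forest import VoteMatrix, per_tree_predictions


def vm(counts, labels=("a", "b")):
    counts = np.asarray(counts, dtype=np.int64)
    return VoteMatrix(
        counts=counts,
        denominators=counts.sum(axis=1),
        label_order=list(labels),
    )


# -- vote-margin accuracy ----------------------------------------------------


def test_accuracy_unanimous_correct():
    assert vote_margin_accuracy(vm([[5, 0], [0, 5]]), ["a", "b"]) == 1.0


def test_accuracy_tie_counts_as_error():
    assert vote_margin_accuracy(vm([[5, 5]]), ["a"]) == 0.0


def test_accuracy_direct_evaluation():
    # rows {Q=(7,3), y=a}, {Q=(2,8), y=a} -> one strict win of the true class
    assert vote_margin_accuracy(vm([[7, 3], [2, 8]]), ["a", "a"]) == 0.5


def test_accuracy_excludes_zero_vote_rows():
    m = vm([[4, 0], [0, 0]])
    assert vote_margin_accuracy(m, ["a", "a"]) == 1.0


# -- AUC ---------------------------------------------------------------------


def test_auc_perfect_separation():
    assert binary_auc([0.9, 0.8, 0.2, 0.1], ["p", "p", "q", "q"],
                      positive_label="p") == 1.0


def test_auc_all_ties_half():
    assert binary_auc([0.5, 0.5, 0.5, 0.5], ["p", "q", "p", "q"],
                      positive_label="p") == 0.5


def test_auc_pairwise_concordance():
    assert binary_auc([0.9, 0.4, 0.6], ["+", "-", "+"], positive_label="+") == 1.0
    # both positive/negative pairs discordant -> 0 of 2 concordant
    assert binary_auc([0.4, 0.9, 0.6], ["+", "-", "+"], positive_label="+") == 0.0
    # exactly 1 of 4 pairs concordant
    assert binary_auc(
        [0.4, 0.8, 0.6, 0.9], ["+", "+", "-", "-"], positive_label="+"
    ) == 0.25


def test_auc_rejects_single_class():
    with pytest.raises(ValidationError):
        binary_auc([0.4, 0.6], ["p", "p"])


# -- margins -----------------------------------------------------------------


def test_margin_unanimous():
    mr, keep = margins(vm([[10, 0]]), ["a"])
    assert mr.tolist() == [1.0] and keep.all()
    mr, _ = margins(vm([[10, 0]]), ["b"])
    assert mr.tolist() == [-1.0]


def test_margin_direct_value():
    mr, _ = margins(vm([[6, 4]]), ["a"])
    assert mr[0] == pytest.approx(0.2)


def test_margin_excludes_zero_denominator():
    mr, keep = margins(vm([[6, 4], [0, 0]]), ["a", "a"])
    assert mr.shape == (1,)
    assert keep.tolist() == [True, False]


# -- strength / correlation / c/s^2 -------------------------------------------


def test_perfect_forest_diagnostics():
    """Unanimous correct OOB votes: s = 1, rho = 0, c/s^2 = 0."""
    oob = vm([[3, 0], [3, 0], [0, 3]])
    y = ["a", "a", "b"]
    per_tree = [
        (np.array([0, 1, 2]), np.array([0, 0, 1])) for _ in range(3)
    ]
    s, rho, cs2 = strength_correlation(oob, y, per_tree)
    assert (s, rho, cs2) == (1.0, 0.0, 0.0)


def test_constant_margins_zero_correlation():
    # margins all 1/3 but < 1: zero variance numerator -> rho = 0
    oob = vm([[2, 1], [2, 1], [1, 2]])
    y = ["a", "a", "b"]
    per_tree = [
        (np.array([0, 1, 2]), np.array([0, 0, 1])),
        (np.array([0, 1, 2]), np.array([0, 1, 0])),
        (np.array([0, 1, 2]), np.array([1, 0, 1])),
    ]
    s, rho, cs2 = strength_correlation(oob, y, per_tree)
    assert s == pytest.approx(1 / 3)
    assert rho == 0.0 and cs2 == 0.0


def test_strength_correlation_pinned_fixture():
    """Three trees, six samples, hand-evaluated estimator.

    OOB votes: s0 (1,0) s1 (1,1) s2 (2,0) s3 (1,0) s4 (0,2) s5 (0,1) with
    y = a,a,a,b,b,b. Margins: 1, 0, 1, -1, 1, 1 -> s = 1/2,
    var(mr) = 5/6 - 1/4 = 7/12. Per tree (p1, p2) = (2/3, 1/3), (2/3, 1/3),
    (1, 0) -> sd = sqrt(10)/3, sqrt(10)/3, sqrt(2);
    rho = (7/12) / mean(sd)^2 and c/s^2 = rho / (1/2)^2.
    """
    oob_votes = vm([[1, 0], [1, 1], [2, 0], [1, 0], [0, 2], [0, 1]])
    y = ["a", "a", "a", "b", "b", "b"]
    per_tree = [
        (np.array([0, 1, 2]), np.array([0, 1, 0])),
        (np.array([1, 3, 4]), np.array([0, 0, 1])),
        (np.array([2, 4, 5]), np.array([0, 1, 1])),
    ]
    s, rho, cs2 = strength_correlation(oob_votes, y, per_tree)
    assert s == pytest.approx(0.5)
    mean_sd = (2 * math.sqrt(10) / 3 + math.sqrt(2)) / 3
    rho_expected = (7 / 12) / mean_sd**2
    assert rho == pytest.approx(rho_expected)
    assert cs2 == pytest.approx(rho_expected / 0.25)


def test_nonpositive_strength_flags_cs2():
    oob = vm([[0, 3], [0, 3]])  # every vote wrong
    per_tree = [(np.array([0, 1]), np.array([1, 1])) for _ in range(3)]
    s, rho, cs2 = strength_correlation(oob, ["a", "a"], per_tree)
    assert s == -1.0
    assert math.isnan(cs2)


def test_oob_accuracy_equals_positive_margin_fraction(separable_dataset):
    """Vote-margin accuracy of OOB votes equals the fraction of samples with
    strictly positive margin (same strict inequality)."""
    d = separable_dataset
    forest = fit_forest(d, K=30, sampler=uniform_sampler(5, 2), seed=17)
    oob_vm = votes(forest, d.values, oob_only=True)
    acc = vote_margin_accuracy(oob_vm, d.labels)
    mr, _ = margins(oob_vm, d.labels)
    assert acc == pytest.approx(np.mean(mr > 0))


def test_forest_diagnostics_strength_is_mean_margin(separable_dataset):
    d = separable_dataset
    forest = fit_forest(d, K=30, sampler=uniform_sampler(5, 2), seed=18)
    diag = forest_diagnostics(forest, d)
    assert diag.strength == pytest.approx(diag.margins.mean())
    preds = per_tree_predictions(forest, d.values)
    assert preds.shape == (30, d.n_samples)


# -- cross-validation harness -------------------------------------------------


def test_baseline_mtry_formula():
    assert baseline_mtry(2000) == 11  # floor(log2(2000) + 1)
    assert baseline_mtry(500) == 9


@pytest.fixture(scope="module")
def cv_table(small_signal_truth):
    params = TsRFParams(R=6, K_screen=30, mtry_screen=12, K=20, seed=21)
    return kfold_cv(small_signal_truth.dataset, k=4, params=params, seed=21)


def test_kfold_rows_and_models(cv_table):
    assert len(cv_table) == 8  # 4 folds x 2 models
    assert set(cv_table["model"]) == {"ts-RF", "RF"}
    assert ((cv_table["accuracy"] >= 0) & (cv_table["accuracy"] <= 1)).all()


def test_kfold_deterministic(small_signal_truth, cv_table):
    params = TsRFParams(R=6, K_screen=30, mtry_screen=12, K=20, seed=21)
    again = kfold_cv(small_signal_truth.dataset, k=4, params=params, seed=21)
    assert again.equals(cv_table)


def test_kfold_stratified_partition(small_signal_truth):
    from sklearn.model_selection import StratifiedKFold

    d = small_signal_truth.dataset
    skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=21)
    seen = []
    global_case_frac = np.mean(d.labels == "case")
    for _, te in skf.split(d.values, d.labels):
        seen.extend(te.tolist())
        fold_frac = np.mean(d.labels[te] == "case")
        assert abs(fold_frac - global_case_frac) * te.size <= 1.0
    assert sorted(seen) == list(range(d.n_samples))


def test_kfold_rejects_small_classes(tiny_genotype):
    with pytest.raises(ValidationError):
        kfold_cv(tiny_genotype, k=5)
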