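"""Forest performance measures and the cross-validated model comparison.

Test-side measures: vote-margin accuracy (a sample counts as correct only
when the true class strictly out-votes every other class) and rank-based
binary AUC. Training-side (out-of-bag) measures are Breiman's forest
diagnostics: the strength ``s`` (mean OOB margin), the mean tree correlation
``rho`` and the generalization-error bound ``c/s^2 = rho / s^2`` — a lower
bound indicates a forest of strong yet weakly correlated trees.

The k-fold harness refits the *entire* pipeline, including both screening
stages, inside every training fold, so no feature-selection information leaks
from test to train.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset
from .errors import ValidationError
from .forest import (
    Forest,
    VoteMatrix,
    fit_forest,
    per_tree_predictions,
    uniform_sampler,
    votes,
)
from .model import TsRFParams, fit_tsrf

logger = logging.getLogger(__name__)

__all__ = [
    "ForestDiagnostics",
    "test_accuracy",
    "binary_auc",
    "margins",
    "strength_correlation",
    "forest_diagnostics",
    "baseline_mtry",
    "kfold_cv",
]


@dataclass
class ForestDiagnostics:
    """OOB diagnostics of a fitted forest plus optional test-side metrics."""

    strength: float
    mean_correlation: float
    cs2: float  # NaN when strength <= 0 (bound undefined)
    accuracy: float
    auc: float  # NaN for non-binary problems
    margins: np.ndarray


def _codes(labels, label_order: list[str]) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(label_order)}
    try:
        return np.fromiter((lut[str(y)] for y in labels), dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} not in model classes") from None


def test_accuracy(vm: VoteMatrix, true_labels) -> float:
    """Vote-margin accuracy: fraction of samples whose true class strictly
    out-votes the best wrong class (a tie counts as an error).

    Rows with zero voting trees are excluded (and counted in the log).
    """
    y = _codes(true_labels, vm.label_order)
    if y.size != vm.counts.shape[0]:
        raise ValidationError("labels do not align with the vote matrix")
    keep = vm.defined
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("test_accuracy: excluded %d zero-vote samples", dropped)
    if not keep.any():
        raise ValidationError("no samples received any votes")
    counts = vm.counts[keep]
    yk = y[keep]
    true_votes = counts[np.arange(yk.size), yk]
    masked = counts.copy()
    masked[np.arange(yk.size), yk] = -1
    best_other = masked.max(axis=1)
    return float(np.mean(true_votes - best_other > 0))


def binary_auc(scores, labels, positive_label: str | None = None) -> float:
    """Rank-based (Mann-Whitney) AUC with ties contributing 1/2.

    ``scores`` are the vote fractions of the positive class; by default the
    positive class is the first label in canonical (sorted) order.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray([str(y) for y in labels], dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"binary AUC needs exactly 2 classes, got {classes}")
    pos = positive_label if positive_label is not None else classes[0]
    is_pos = labels == pos
    n_pos = int(is_pos.sum())
    n_neg = is_pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def margins(oob_votes: VoteMatrix, true_labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample OOB margin ``Q(x,y)/den - max_{j != y} Q(x,j)/den``.

    Returns ``(margins, included_mask)``; samples with zero OOB votes are
    excluded from the margin vector and flagged False in the mask.
    """
    y = _codes(true_labels, oob_votes.label_order)
    keep = oob_votes.defined
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("margins: excluded %d never-out-of-bag samples", dropped)
    frac = oob_votes.fractions()[keep]
    yk = y[keep]
    true_frac = frac[np.arange(yk.size), yk]
    masked = frac.copy()
    masked[np.arange(yk.size), yk] = -np.inf
    return true_frac - masked.max(axis=1), keep


def _runner_up(oob_votes: VoteMatrix, y: np.ndarray) -> np.ndarray:
    """Most-voted wrong class per sample (ties to the smallest code)."""
    masked = oob_votes.counts.copy()
    masked[np.arange(y.size), y] = -1
    return np.argmax(masked, axis=1)


def strength_correlation(
    oob_votes: VoteMatrix,
    true_labels,
    per_tree_oob_predictions: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float, float]:
    """Breiman's OOB strength ``s``, mean correlation ``rho`` and ``c/s^2``.

    ``per_tree_oob_predictions`` holds ``(oob_index_array, predicted_codes)``
    per tree. With margins ``mr``: ``s = mean(mr)``;
    ``rho = var(mr) / (mean_k sd_k)^2`` where, over tree k's usable OOB
    samples, ``p1_k`` is the fraction predicted correctly, ``p2_k`` the
    fraction predicted as the sample's most-voted wrong class, and
    ``sd_k = sqrt(p1_k + p2_k + (p1_k - p2_k)^2)``; ``c/s^2 = rho / s^2``
    (NaN, with a warning, when ``s <= 0``).
    """
    y = _codes(true_labels, oob_votes.label_order)
    mr, keep = margins(oob_votes, true_labels)
    if mr.size < 2:
        raise ValidationError("need at least 2 samples with OOB votes")
    s = float(mr.mean())
    var_mr = float(mr.var())  # population variance, E[mr^2] - s^2
    jhat = _runner_up(oob_votes, y)
    sds = []
    for oob, preds in per_tree_oob_predictions:
        usable = oob[keep[oob]]
        if usable.size == 0:
            continue
        pk = preds[keep[oob]] if preds.size == oob.size else preds[usable]
        p1 = float(np.mean(pk == y[usable]))
        p2 = float(np.mean(pk == jhat[usable]))
        sds.append(math.sqrt(p1 + p2 + (p1 - p2) ** 2))
    if not sds:
        raise ValidationError("no tree has usable out-of-bag samples")
    mean_sd = float(np.mean(sds))
    rho = 0.0 if var_mr == 0.0 else var_mr / (mean_sd**2)
    if s <= 0:
        logger.warning("strength <= 0: c/s^2 bound undefined")
        cs2 = math.nan
    else:
        cs2 = rho / (s**2)
    return s, rho, cs2


def forest_diagnostics(
    forest: Forest,
    train: LabeledDataset,
    test: LabeledDataset | None = None,
    positive_label: str | None = None,
) -> ForestDiagnostics:
    """Compute OOB strength/correlation/c/s^2 on the training set and, when a
    test set is given, vote-margin accuracy and AUC on it."""
    oob_vm = votes(forest, train.values, oob_only=True)
    preds = per_tree_predictions(forest, train.values)
    per_tree = [
        (oob, preds[k][oob]) for k, oob in enumerate(forest.oob_indices)
    ]
    s, rho, cs2 = strength_correlation(oob_vm, train.labels, per_tree)
    mr, _ = margins(oob_vm, train.labels)
    if test is not None:
        vm = votes(forest, test.values, oob_only=False)
        acc = test_accuracy(vm, test.labels)
        if len(forest.label_order) == 2:
            pos = positive_label or forest.label_order[0]
            scores = vm.fractions()[:, forest.label_order.index(pos)]
            auc = binary_auc(scores, test.labels, positive_label=pos)
        else:
            auc = math.nan
    else:
        acc = test_accuracy(oob_vm, train.labels)
        auc = math.nan
    return ForestDiagnostics(
        strength=s,
        mean_correlation=rho,
        cs2=cs2,
        accuracy=acc,
        auc=auc,
        margins=mr,
    )


def baseline_mtry(n_features: int) -> int:
    """Classic small default subspace size ``floor(log2 M + 1)``."""
    return int(math.floor(math.log2(n_features) + 1))


def kfold_cv(
    d: LabeledDataset,
    k: int = 5,
    params: TsRFParams = TsRFParams(),
    seed: int = 0,
    baseline_trees: int | None = None,
) -> pd.DataFrame:
    """Stratified k-fold comparison of ts-RF against the plain-RF baseline.

    The two-stage screen is re-run from scratch on every training fold. The
    baseline is a plain forest (same tree code) with uniform subspaces of
    size ``floor(log2 M + 1)`` over all features and the same tree count.

    Returns one row per (fold, model) with test accuracy, AUC (binary) and
    the training-fold OOB strength / correlation / c/s^2.
    """
    if k < 2:
        raise ValidationError("need k >= 2 folds")
    y = d.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"every class needs >= {k} members for {k}-fold CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    m = d.n_features
    rows = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(d.values, y)):
        train = d.subset_samples(tr_idx)
        test = d.subset_samples(te_idx)
        fold_params = replace(
            params, seed=int((params.seed * 1009 + fold) % 2**31)
        )
        ts_model = fit_tsrf(train, fold_params)
        ts_diag = forest_diagnostics(ts_model.forest, train, test)
        rows.append(_row(fold, "ts-RF", ts_diag))
        rf = fit_forest(
            train,
            K=baseline_trees or params.K,
            sampler=uniform_sampler(m, baseline_mtry(m)),
            n_min=params.n_min,
            seed=(fold_params.seed, 3),
        )
        rf_diag = forest_diagnostics(rf, train, test)
        rows.append(_row(fold, "RF", rf_diag))
    return pd.DataFrame(rows)


def _row(fold: int, model: str, diag: ForestDiagnostics) -> dict:
    return {
        "fold": fold,
        "model": model,
        "accuracy": diag.accuracy,
        "auc": diag.auc,
        "strength": diag.strength,
        "correlation": diag.mean_correlation,
        "cs2": diag.cs2,
    }
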