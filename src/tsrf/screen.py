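"""Two-stage quality-based feature screen and the stratified node sampler.

Stage 1 separates informative from noisy features using *shadow* features:
each original column is duplicated as an independent row-permutation of
itself, which preserves its marginal distribution while destroying any label
association. Over ``R`` replicates, a forest is grown on the 2M-column
extended matrix and raw Gini importances are collected; per replicate, the
maximum importance over all shadows forms the noise reference. A feature is
kept (enters the informative set) when a one-sided Wilcoxon rank-sum test
says its ``R`` importance scores are stochastically greater than the ``R``
shadow maxima at level ``theta`` — i.e. it must consistently beat the *best*
noise column across permutations, a deliberately conservative screen.

Stage 2 splits the informative set by a per-feature Pearson chi-squared
association test against the class label: features with ``p <= alpha``
(default 0.05) form the strong group, the rest the weak group. At every tree
node, ``mtry_s`` candidates are drawn from the strong group and ``mtry_w``
from the weak group, with group quotas proportional to group sizes — so every
node subspace contains at least one strongly associated feature whenever any
exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CONTINUOUS, GENOTYPE, LabeledDataset
from .errors import ValidationError
from .forest import fit_forest, raw_importance, uniform_sampler
from .tree import SubspaceSampler

__all__ = [
    "ImportanceReplicates",
    "ScreenResult",
    "make_shadow_extended",
    "importance_replicates",
    "wilcoxon_greater_pvalue",
    "stage1_filter",
    "chi2_association_pvalue",
    "stage2_partition",
    "subspace_sizes",
    "draw_stratified_subspace",
    "stratified_subspace_sampler",
    "run_screen",
    "write_screen_report",
]

SHADOW_SUFFIX = "__shadow"


@dataclass
class ImportanceReplicates:
    """Raw importance scores from ``R`` independent shadow-extended forests."""

    real_scores: np.ndarray  # (R, M) importances of the original features
    shadow_max: np.ndarray  # (R,) max shadow importance per replicate
    R: int
    K_screen: int
    mtry_screen: int


@dataclass
class ScreenResult:
    """Outcome of both screening stages for one training set.

    Arrays are indexed by original feature position; ``chi2_p`` is NaN for
    features removed in stage 1 (the association test is only run on
    survivors).
    """

    wilcoxon_p: np.ndarray  # (M,)
    theta: float
    informative: np.ndarray  # sorted indices of the surviving set
    chi2_p: np.ndarray  # (M,), NaN outside `informative`
    strong: np.ndarray  # sorted indices, chi2_p <= alpha
    weak: np.ndarray  # sorted indices, the remainder of `informative`
    alpha: float
    mean_importance: np.ndarray  # (M,) mean replicate importance

    def group_of(self, f: int) -> str:
        if f in set(self.strong.tolist()):
            return "strong"
        if f in set(self.weak.tolist()):
            return "weak"
        return "removed"

    def to_dict(self) -> dict:
        return {
            "wilcoxon_p": self.wilcoxon_p.tolist(),
            "theta": self.theta,
            "informative": self.informative.tolist(),
            "chi2_p": [None if np.isnan(p) else p for p in self.chi2_p],
            "strong": self.strong.tolist(),
            "weak": self.weak.tolist(),
            "alpha": self.alpha,
            "mean_importance": self.mean_importance.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenResult":
        return cls(
            wilcoxon_p=np.asarray(d["wilcoxon_p"], dtype=np.float64),
            theta=d["theta"],
            informative=np.asarray(d["informative"], dtype=np.int64),
            chi2_p=np.asarray(
                [np.nan if p is None else p for p in d["chi2_p"]],
                dtype=np.float64,
            ),
            strong=np.asarray(d["strong"], dtype=np.int64),
            weak=np.asarray(d["weak"], dtype=np.int64),
            alpha=d["alpha"],
            mean_importance=np.asarray(d["mean_importance"], dtype=np.float64),
        )


def make_shadow_extended(
    d: LabeledDataset, rng: np.random.Generator
) -> LabeledDataset:
    """Append one permuted shadow column per original feature (2M total)."""
    n, m = d.values.shape
    # an independent uniform permutation per column
    perms = np.argsort(rng.random((n, m)), axis=0)
    shadows = d.values[perms, np.arange(m)]
    return LabeledDataset(
        values=np.hstack([d.values, shadows]),
        feature_ids=list(d.feature_ids)
        + [f"{f}{SHADOW_SUFFIX}" for f in d.feature_ids],
        sample_ids=list(d.sample_ids),
        labels=d.labels,
        feature_kind=d.feature_kind,
    )


def default_mtry_screen(m_features: int) -> int:
    """Screen-forest subspace size: 0.1·M (at least 1)."""
    return max(1, int(0.1 * m_features))


def importance_replicates(
    d: LabeledDataset,
    R: int = 30,
    K_screen: int = 50,
    mtry_screen: int | None = None,
    n_min: int = 1,
    seed: int | Sequence[int] = 0,
) -> ImportanceReplicates:
    """Fit ``R`` forests on freshly shadow-extended data, collect importances.

    Each replicate re-permutes the shadows (a new noise draw) and fits
    ``K_screen`` trees with plain uniform subspace sampling of size
    ``mtry_screen`` over all 2M columns.
    """
    if R < 2:
        raise ValidationError("need R >= 2 replicates for the rank-sum screen")
    m = d.n_features
    if mtry_screen is None:
        mtry_screen = default_mtry_screen(m)
    seed_list = [int(seed)] if isinstance(seed, (int, np.integer)) else [
        int(s) for s in seed
    ]
    real = np.empty((R, m))
    shadow_max = np.empty(R)
    for r in range(R):
        rng = np.random.default_rng(seed_list + [7919, r])
        ext = make_shadow_extended(d, rng)
        forest = fit_forest(
            ext,
            K=K_screen,
            sampler=uniform_sampler(2 * m, min(mtry_screen, 2 * m)),
            n_min=n_min,
            seed=tuple(seed_list + [104729, r]),
        )
        imp = raw_importance(forest)
        real[r] = imp[:m]
        shadow_max[r] = imp[m:].max()
    return ImportanceReplicates(
        real_scores=real,
        shadow_max=shadow_max,
        R=R,
        K_screen=K_screen,
        mtry_screen=mtry_screen,
    )


def wilcoxon_greater_pvalue(x, y) -> float:
    """One-sided two-sample Wilcoxon rank-sum p-value, alternative
    "x stochastically greater than y".

    Exact (full rank-assignment distribution) when the pooled sample has at
    most 12 observations and no ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test needs nonempty samples")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return 1.0  # all observations tied: no evidence in either direction
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="greater", method=method, use_continuity=True
    )
    return float(res.pvalue)


def stage1_filter(
    rep: ImportanceReplicates, theta: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature rank-sum p-values against the shadow maxima and the
    surviving informative set ``{f : p <= theta}`` (boundary retained)."""
    if not 0.0 < theta < 1.0:
        raise ValidationError("theta must lie in (0, 1)")
    m = rep.real_scores.shape[1]
    pvals = np.empty(m)
    for f in range(m):
        pvals[f] = wilcoxon_greater_pvalue(rep.real_scores[:, f], rep.shadow_max)
    informative = np.flatnonzero(pvals <= theta)
    return pvals, informative


def _tertile_codes(col: np.ndarray) -> np.ndarray:
    cuts = np.quantile(col, [1.0 / 3.0, 2.0 / 3.0])
    return np.digitize(col, cuts, right=True)


def chi2_association_pvalue(
    feature_column,
    labels,
    feature_kind: str = GENOTYPE,
) -> tuple[float, float]:
    """Pearson chi-squared association of one feature with the class label.

    Genotype columns are tabulated on their observed dosage values;
    continuous columns are first discretised into tertiles. No continuity
    correction; zero-margin categories are dropped. A constant feature has
    statistic 0 and p-value 1.
    """
    col = np.asarray(feature_column, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("chi-squared association needs >= 2 classes")
    if feature_kind == CONTINUOUS:
        col = _tertile_codes(col)
    cats, cat_codes = np.unique(col, return_inverse=True)
    _, lab_codes = np.unique(labels, return_inverse=True)
    if cats.size < 2:
        return 0.0, 1.0
    table = np.zeros((cats.size, lab_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (cat_codes, lab_codes), 1)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if min(table.shape) < 2:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def stage2_partition(
    d: LabeledDataset,
    informative: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the informative set into strong (``chi2 p <= alpha``) and weak.

    Returns ``(strong, weak, chi2_p)`` with ``chi2_p`` indexed over all M
    features (NaN outside the informative set).
    """
    informative = np.asarray(informative, dtype=np.int64)
    if informative.size == 0:
        raise ValidationError("informative set is empty")
    chi2_p = np.full(d.n_features, np.nan)
    for f in informative:
        _, chi2_p[f] = chi2_association_pvalue(
            d.values[:, f], d.labels, d.feature_kind
        )
    strong = informative[chi2_p[informative] <= alpha]
    weak = np.setdiff1d(informative, strong)
    return strong, weak, chi2_p


def subspace_sizes(mtry: int, n_strong: int, n_weak: int) -> tuple[int, int]:
    """Group quotas ``(mtry_s, mtry_w)`` proportional to group sizes.

    ``mtry_s = max(1, floor(mtry * n_strong / (n_strong + n_weak)))`` when the
    strong group is nonempty (so every node sees a strong candidate), the
    remainder goes to the weak group; each quota is capped at its group size
    and a degenerate (empty) group receives 0.
    """
    if n_strong < 0 or n_weak < 0:
        raise ValidationError("group sizes must be nonnegative")
    if n_strong + n_weak == 0:
        raise ValidationError("both feature groups are empty")
    if n_strong == 0:
        return 0, min(mtry, n_weak)
    if n_weak == 0:
        return min(mtry, n_strong), 0
    if mtry < 2:
        raise ValidationError("mtry must be >= 2 when both groups are nonempty")
    mtry_s = max(1, (mtry * n_strong) // (n_strong + n_weak))
    mtry_w = mtry - mtry_s
    mtry_s = min(mtry_s, n_strong)
    mtry_w = min(mtry_w, n_weak)
    return mtry_s, mtry_w


def draw_stratified_subspace(
    X_s,
    X_w,
    mtry_s: int,
    mtry_w: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One node subspace: uniform without-replacement draws from each group."""
    strong = np.asarray(X_s, dtype=np.int64)
    weak = np.asarray(X_w, dtype=np.int64)
    if mtry_s > strong.size or mtry_w > weak.size:
        raise ValidationError("subspace size exceeds group size")
    parts = []
    if mtry_s:
        parts.append(rng.choice(strong, size=mtry_s, replace=False))
    if mtry_w:
        parts.append(rng.choice(weak, size=mtry_w, replace=False))
    return np.concatenate(parts)


def stratified_subspace_sampler(
    X_s, X_w, mtry_s: int, mtry_w: int
) -> SubspaceSampler:
    """Sampler closure for tree growth over a fixed strong/weak partition."""
    strong = np.sort(np.asarray(X_s, dtype=np.int64))
    weak = np.sort(np.asarray(X_w, dtype=np.int64))
    if mtry_s > strong.size or mtry_w > weak.size:
        raise ValidationError("subspace size exceeds group size")

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return draw_stratified_subspace(strong, weak, mtry_s, mtry_w, rng)

    return sampler


def run_screen(
    d: LabeledDataset,
    R: int = 30,
    K_screen: int = 50,
    mtry_screen: int | None = None,
    theta: float = 0.05,
    alpha: float = 0.05,
    n_min: int = 1,
    seed: int | Sequence[int] = 0,
) -> ScreenResult:
    """Run both stages on a training set and bundle the outcome.

    Raises nothing when the informative set is empty — the result simply has
    an empty ``informative`` array; model fitting is where that becomes an
    error (so callers can still inspect the p-values).
    """
    rep = importance_replicates(
        d, R=R, K_screen=K_screen, mtry_screen=mtry_screen, n_min=n_min, seed=seed
    )
    wilcoxon_p, informative = stage1_filter(rep, theta)
    if informative.size:
        strong, weak, chi2_p = stage2_partition(d, informative, alpha)
    else:
        strong = weak = np.asarray([], dtype=np.int64)
        chi2_p = np.full(d.n_features, np.nan)
    return ScreenResult(
        wilcoxon_p=wilcoxon_p,
        theta=theta,
        informative=informative,
        chi2_p=chi2_p,
        strong=strong,
        weak=weak,
        alpha=alpha,
        mean_importance=rep.real_scores.mean(axis=0),
    )


def screen_report(result: ScreenResult, feature_ids: list[str]) -> pd.DataFrame:
    """Ranked per-feature report: rank, feature_id, group, wilcoxon_p, chi2_p.

    Ordered by mean replicate importance (descending), ties by Wilcoxon
    p-value ascending then feature index.
    """
    m = len(feature_ids)
    order = sorted(
        range(m),
        key=lambda f: (-result.mean_importance[f], result.wilcoxon_p[f], f),
    )
    strong = set(result.strong.tolist())
    weak = set(result.weak.tolist())
    rows = []
    for rank, f in enumerate(order, start=1):
        group = "strong" if f in strong else "weak" if f in weak else "removed"
        rows.append(
            {
                "rank": rank,
                "feature_id": feature_ids[f],
                "group": group,
                "importance": result.mean_importance[f],
                "wilcoxon_p": result.wilcoxon_p[f],
                "chi2_p": result.chi2_p[f],
            }
        )
    return pd.DataFrame(rows)


def write_screen_report(
    result: ScreenResult, feature_ids: list[str], path: str | Path
) -> None:
    screen_report(result, feature_ids).to_csv(path, sep="\t", index=False)
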