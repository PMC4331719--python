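"""End-to-end two-stage quality-based random forest (ts-RF).

Training runs the full pipeline on one training set:

1. extend the data with shadow features and collect ``R`` replicate
   importance matrices (stage 1 inputs);
2. Wilcoxon-screen each feature against the per-replicate shadow maxima at
   level ``theta``; survivors form the informative set;
3. chi-squared partition the survivors into strong/weak groups at ``alpha``;
4. grow ``K`` bagged CART trees whose per-node candidate subspaces draw
   ``mtry_s`` strong and ``mtry_w`` weak features (quotas proportional to
   group sizes);
5. predict new samples by majority vote over the forest.

The fitted model is a pure function of ``(training data, params)`` including
the seed, and serialises to a single JSON file that reproduces predictions
exactly on reload.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .errors import NoInformativeFeaturesError, ValidationError
from .forest import Forest, VoteMatrix, fit_forest, predict_forest, votes
from .screen import (
    ScreenResult,
    run_screen,
    screen_report,
    stratified_subspace_sampler,
    subspace_sizes,
)

__all__ = ["TsRFParams", "TsRFModel", "fit_tsrf", "predict_tsrf", "vote_scores",
           "rank_features"]


@dataclass(frozen=True)
class TsRFParams:
    """Hyperparameters of the two-stage forest.

    ``mtry=None`` resolves to ``floor(sqrt(|informative set|))`` (at least 2
    when both groups are nonempty); ``mtry_screen=None`` resolves to
    ``0.1 * M``.
    """

    R: int = 30
    theta: float = 0.05
    alpha: float = 0.05
    K: int = 500
    mtry: int | None = None
    n_min: int = 1
    K_screen: int = 50
    mtry_screen: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.theta < 1.0 and 0.0 < self.alpha < 1.0):
            raise ValidationError("theta and alpha must lie in (0, 1)")
        if self.K < 1 or self.R < 1:
            raise ValidationError("K and R must be >= 1")
        if self.n_min < 1:
            raise ValidationError("n_min must be >= 1")


def resolve_mtry(params: TsRFParams, n_informative: int) -> int:
    if params.mtry is not None:
        return min(params.mtry, n_informative)
    return min(max(2, int(math.isqrt(n_informative))), n_informative)


@dataclass
class TsRFModel:
    screen: ScreenResult
    forest: Forest
    params: TsRFParams
    feature_ids: list[str]
    label_order: list[str]
    mtry_s: int = 0
    mtry_w: int = 0

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "tsrf-model-v1",
            "params": asdict(self.params),
            "feature_ids": self.feature_ids,
            "label_order": self.label_order,
            "mtry_s": self.mtry_s,
            "mtry_w": self.mtry_w,
            "screen": self.screen.to_dict(),
            "forest": self.forest.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TsRFModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "tsrf-model-v1":
            raise ValidationError(f"{path}: not a ts-RF model file")
        return cls(
            screen=ScreenResult.from_dict(payload["screen"]),
            forest=Forest.from_dict(payload["forest"]),
            params=TsRFParams(**payload["params"]),
            feature_ids=list(payload["feature_ids"]),
            label_order=list(payload["label_order"]),
            mtry_s=payload["mtry_s"],
            mtry_w=payload["mtry_w"],
        )


def fit_tsrf(train: LabeledDataset, params: TsRFParams = TsRFParams()) -> TsRFModel:
    """Fit the full two-stage model on ``train``.

    Raises
    ------
    NoInformativeFeaturesError
        When no feature survives the stage-1 screen at ``params.theta``;
        lower ``theta`` only with care — a dataset of pure noise *should*
        land here.
    """
    params.validate()
    screen = run_screen(
        train,
        R=params.R,
        K_screen=params.K_screen,
        mtry_screen=params.mtry_screen,
        theta=params.theta,
        alpha=params.alpha,
        n_min=params.n_min,
        seed=(params.seed, 1),
    )
    if screen.informative.size == 0:
        raise NoInformativeFeaturesError(
            f"no informative features at theta={params.theta}: every feature's "
            "importance is indistinguishable from the shadow maxima; the data "
            "may carry no signal (or raise theta/R deliberately)"
        )
    mtry = resolve_mtry(params, screen.informative.size)
    mtry_s, mtry_w = subspace_sizes(mtry, screen.strong.size, screen.weak.size)
    sampler = stratified_subspace_sampler(
        screen.strong, screen.weak, mtry_s, mtry_w
    )
    forest = fit_forest(
        train,
        K=params.K,
        sampler=sampler,
        n_min=params.n_min,
        seed=(params.seed, 2),
    )
    return TsRFModel(
        screen=screen,
        forest=forest,
        params=params,
        feature_ids=list(train.feature_ids),
        label_order=train.label_order,
        mtry_s=mtry_s,
        mtry_w=mtry_w,
    )


def _check_width(model: TsRFModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != len(model.feature_ids):
        raise ValidationError(
            f"expected {len(model.feature_ids)} features, got {X.shape[1]}"
        )
    return X


def predict_tsrf(model: TsRFModel, X) -> np.ndarray:
    """Majority-vote class labels for the rows of ``X``."""
    if isinstance(X, LabeledDataset):
        X = X.values
    return predict_forest(model.forest, _check_width(model, X))


def vote_scores(model: TsRFModel, X) -> np.ndarray:
    """Per-class vote fractions (rows sum to 1); column order is
    ``model.label_order``. Column 0's fraction is the binary AUC score."""
    if isinstance(X, LabeledDataset):
        X = X.values
    vm: VoteMatrix = votes(model.forest, _check_width(model, X), oob_only=False)
    return vm.fractions()


def rank_features(model: TsRFModel, top_n: int = 25) -> pd.DataFrame:
    """Ranked feature report (mean replicate importance descending, ties by
    Wilcoxon p then index), truncated to ``top_n`` rows."""
    if top_n < 0:
        raise ValidationError("top_n must be >= 0")
    report = screen_report(model.screen, model.feature_ids)
    return report.head(top_n).reset_index(drop=True)
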