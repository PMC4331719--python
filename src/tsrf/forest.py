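"""Bagged forest of CART trees: fitting, voting, OOB bookkeeping, importance.

Every tree ``k`` draws its bootstrap sample and all of its node subspaces from
a private RNG stream keyed by ``(seed, k)``, so the forest is a pure function
of ``(data, parameters, seed)`` and is identical no matter in which order —
or on how many workers — the trees are materialised.

With a uniform subspace sampler this module *is* the plain random-forest
baseline; the two-stage model reuses it unchanged with a stratified sampler.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data import LabeledDataset
from .tree import SubspaceSampler, Tree, grow_tree

__all__ = [
    "Forest",
    "VoteMatrix",
    "uniform_sampler",
    "fit_forest",
    "votes",
    "predict_forest",
    "raw_importance",
]


def _seed_tuple(seed) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def uniform_sampler(n_features: int, mtry: int) -> SubspaceSampler:
    """Classic RF subspace: ``mtry`` features uniformly without replacement."""
    if not 1 <= mtry <= n_features:
        raise ValueError(f"mtry must lie in [1, {n_features}], got {mtry}")

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return rng.choice(n_features, size=mtry, replace=False)

    return sampler


@dataclass
class VoteMatrix:
    """Per-sample per-class vote counts ``Q(x_i, j)``.

    ``denominators[i]`` is the number of trees that voted for sample ``i``
    (all ``K`` at test time; only the trees holding ``i`` out-of-bag in OOB
    mode, possibly zero).
    """

    counts: np.ndarray  # (N, c) int64
    denominators: np.ndarray  # (N,) int64
    label_order: list[str]

    def __post_init__(self) -> None:
        if (self.counts.sum(axis=1) != self.denominators).any():
            raise ValueError("vote rows must sum to their denominators")

    def fractions(self) -> np.ndarray:
        """Row-normalised votes; rows with zero denominator become NaN."""
        den = self.denominators.astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / den[:, None]
        return out

    @property
    def defined(self) -> np.ndarray:
        """Mask of rows with at least one voting tree."""
        return self.denominators > 0


@dataclass
class Forest:
    trees: list[Tree]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    label_order: list[str]
    seed: tuple[int, ...]
    n_features: int
    n_min: int
    n_train: int
    train_digest: str = ""
    _train_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single JSON file; :meth:`load` reproduces predictions
        exactly (thresholds stored as hex floats)."""
        payload = self.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    def to_dict(self) -> dict:
        def enc_tree(t: Tree) -> dict:
            d = t.to_dict()

            def hexify(node: dict) -> None:
                if not node["leaf"]:
                    node["threshold"] = float(node["threshold"]).hex()
                    hexify(node["left"])
                    hexify(node["right"])

            hexify(d["root"])
            return d

        return {
            "format": "tsrf-forest-v1",
            "label_order": self.label_order,
            "seed": list(self.seed),
            "n_features": self.n_features,
            "n_min": self.n_min,
            "n_train": self.n_train,
            "train_digest": self.train_digest,
            "bootstrap": [b.tolist() for b in self.bootstrap_indices],
            "trees": [enc_tree(t) for t in self.trees],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Forest":
        if payload.get("format") != "tsrf-forest-v1":
            raise ValueError("not a tsrf forest file")

        def dec_tree(d: dict) -> Tree:
            def unhex(node: dict) -> None:
                if not node["leaf"]:
                    node["threshold"] = float.fromhex(node["threshold"])
                    unhex(node["left"])
                    unhex(node["right"])

            unhex(d["root"])
            return Tree.from_dict(d)

        n_train = payload["n_train"]
        boot = [np.asarray(b, dtype=np.int64) for b in payload["bootstrap"]]
        oob = [
            np.setdiff1d(np.arange(n_train), b, assume_unique=False)
            for b in boot
        ]
        return cls(
            trees=[dec_tree(d) for d in payload["trees"]],
            bootstrap_indices=boot,
            oob_indices=oob,
            label_order=list(payload["label_order"]),
            seed=tuple(payload["seed"]),
            n_features=payload["n_features"],
            n_min=payload["n_min"],
            n_train=n_train,
            train_digest=payload.get("train_digest", ""),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Forest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _digest(values: np.ndarray) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(values, dtype=np.float64).tobytes()
    ).hexdigest()


def _grow_member(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    sampler: SubspaceSampler,
    n_min: int,
    seed: tuple[int, ...],
    k: int,
) -> tuple[Tree, np.ndarray]:
    """Grow tree ``k`` from its private ``(seed, k)`` RNG stream."""
    rng = np.random.default_rng(list(seed) + [k])
    n = X.shape[0]
    boot = np.sort(rng.integers(0, n, size=n))
    tree = grow_tree(X[boot], y[boot], n_classes, sampler, n_min, rng)
    return tree, boot


def fit_forest(
    train: LabeledDataset,
    K: int,
    sampler: SubspaceSampler,
    n_min: int = 1,
    seed: int | Sequence[int] = 0,
) -> Forest:
    """Fit ``K`` bagged trees on ``train``.

    Each tree is grown on a size-``N`` bootstrap drawn with replacement; the
    out-of-bag set is the complement. Results do not depend on the order in
    which trees are grown.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if train.n_samples == 0:
        raise ValueError("empty training data")
    seed_t = _seed_tuple(seed)
    X = train.values
    y = train.label_codes()
    c = train.n_classes
    all_idx = np.arange(train.n_samples)
    trees, boots, oobs = [], [], []
    for k in range(K):
        tree, boot = _grow_member(X, y, c, sampler, n_min, seed_t, k)
        trees.append(tree)
        boots.append(boot)
        oobs.append(np.setdiff1d(all_idx, boot))
    return Forest(
        trees=trees,
        bootstrap_indices=boots,
        oob_indices=oobs,
        label_order=train.label_order,
        seed=seed_t,
        n_features=train.n_features,
        n_min=n_min,
        n_train=train.n_samples,
        train_digest=_digest(X),
        _train_values=X,
    )


def per_tree_predictions(forest: Forest, X: np.ndarray) -> np.ndarray:
    """``(K, N)`` matrix of per-tree predicted class codes."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != forest.n_features:
        raise ValueError(
            f"expected {forest.n_features} features, got {X.shape[1]}"
        )
    return np.stack([t.predict(X) for t in forest.trees])


def votes(forest: Forest, X, oob_only: bool = False) -> VoteMatrix:
    """Count per-class votes ``Q(x_i, j)`` over the forest.

    With ``oob_only`` the rows of ``X`` must be the training samples in
    training order, and only trees holding sample ``i`` out-of-bag vote for
    it; rows never out-of-bag get denominator 0 (flagged via
    :attr:`VoteMatrix.defined`).
    """
    if isinstance(X, LabeledDataset):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    c = len(forest.label_order)
    n = X.shape[0]
    if oob_only:
        if n != forest.n_train or (
            forest.train_digest and _digest(X) != forest.train_digest
        ):
            raise ValueError("oob_only votes require the training samples")
    preds = per_tree_predictions(forest, X)  # (K, n)
    counts = np.zeros((n, c), dtype=np.int64)
    if oob_only:
        for k, oob in enumerate(forest.oob_indices):
            np.add.at(counts, (oob, preds[k, oob]), 1)
    else:
        for k in range(forest.n_trees):
            np.add.at(counts, (np.arange(n), preds[k]), 1)
    return VoteMatrix(
        counts=counts,
        denominators=counts.sum(axis=1),
        label_order=list(forest.label_order),
    )


def predict_forest(forest: Forest, X) -> np.ndarray:
    """Majority-vote labels; ties go to the smallest class in canonical
    order (argmax returns the first maximum)."""
    vm = votes(forest, X, oob_only=False)
    codes = np.argmax(vm.counts, axis=1)
    labels = np.asarray(forest.label_order, dtype=object)
    return labels[codes]


def raw_importance(forest: Forest) -> np.ndarray:
    """Mean over trees of the summed per-tree Gini decreases per feature.

    Features never chosen for a split score exactly 0; all scores are >= 0.
    """
    imp = np.zeros(forest.n_features)
    for t in forest.trees:
        for f, dec in t.feature_decrease.items():
            imp[f] += dec
    return imp / forest.n_trees
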