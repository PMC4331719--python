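"""Single unpruned CART classification tree with injectable node subspaces.

The tree is standard CART with Gini impurity, except that the candidate
features considered at every internal node come from a caller-supplied
*subspace sampler* — the hook through which both plain uniform sampling and
the stratified strong/weak sampling are implemented.

Numeric conventions (applied uniformly to dosage and continuous features):

* thresholds are midpoints between consecutive distinct sorted values and
  samples with ``value <= threshold`` route left;
* the split minimising the weighted child Gini is chosen, ties broken by
  lower feature index then lower threshold (near-ties are re-compared with
  exact integer arithmetic so float round-off cannot flip the choice);
* a node becomes a leaf when pure, when it has ``<= n_min`` samples, or when
  every candidate feature is constant within the node;
* each split records the impurity decrease
  ``(N(t)/N_root) * (Gini(t) - Gini_split(t))`` against its feature, the raw
  per-tree importance contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

__all__ = [
    "LeafNode",
    "SplitNode",
    "Tree",
    "gini_impurity",
    "gini_split",
    "best_split",
    "grow_tree",
    "predict_tree",
]

# A sampler maps an RNG to an array of candidate feature indices.
SubspaceSampler = Callable[[np.random.Generator], np.ndarray]


def gini_impurity(class_counts) -> float:
    """Gini index ``1 - sum_j p_j^2`` of a node with the given class counts."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty node has no impurity")
    p = counts / n
    return float(1.0 - (p * p).sum())


def gini_split(left_counts, right_counts) -> float:
    """Weighted child impurity ``(N1/N) Gini(t1) + (N2/N) Gini(t2)``."""
    ln = float(np.sum(left_counts))
    rn = float(np.sum(right_counts))
    if ln <= 0 or rn <= 0:
        raise ValueError("both children must be nonempty")
    n = ln + rn
    return (ln / n) * gini_impurity(left_counts) + (rn / n) * gini_impurity(
        right_counts
    )


@dataclass
class LeafNode:
    predicted_class: int  # integer class code (index into canonical order)
    class_counts: np.ndarray
    n_samples: int


@dataclass
class SplitNode:
    feature_index: int
    threshold: float
    left: "Node"
    right: "Node"
    class_counts: np.ndarray
    n_samples: int


Node = Union[LeafNode, SplitNode]


@dataclass
class Tree:
    """A grown tree plus its accumulated per-feature Gini decreases."""

    root: Node
    n_classes: int
    feature_decrease: dict[int, float] = field(default_factory=dict)

    def predict_one(self, x: np.ndarray) -> int:
        node = self.root
        while isinstance(node, SplitNode):
            node = node.left if x[node.feature_index] <= node.threshold else node.right
        return node.predicted_class

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.fromiter(
            (self.predict_one(X[i]) for i in range(X.shape[0])),
            dtype=np.int64,
            count=X.shape[0],
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(node: Node) -> dict:
            if isinstance(node, LeafNode):
                return {
                    "leaf": True,
                    "pred": int(node.predicted_class),
                    "counts": [int(v) for v in node.class_counts],
                }
            return {
                "leaf": False,
                "feature": int(node.feature_index),
                "threshold": float(node.threshold),
                "counts": [int(v) for v in node.class_counts],
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "n_classes": self.n_classes,
            "root": enc(self.root),
            "feature_decrease": {
                str(k): v for k, v in self.feature_decrease.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Tree":
        def dec(node: dict) -> Node:
            counts = np.asarray(node["counts"], dtype=np.int64)
            if node["leaf"]:
                return LeafNode(
                    predicted_class=node["pred"],
                    class_counts=counts,
                    n_samples=int(counts.sum()),
                )
            return SplitNode(
                feature_index=node["feature"],
                threshold=node["threshold"],
                left=dec(node["left"]),
                right=dec(node["right"]),
                class_counts=counts,
                n_samples=int(counts.sum()),
            )

        return cls(
            root=dec(payload["root"]),
            n_classes=payload["n_classes"],
            feature_decrease={
                int(k): float(v)
                for k, v in payload["feature_decrease"].items()
            },
        )


def _exact_key(left: np.ndarray, right: np.ndarray) -> tuple[int, int]:
    """Exact-integer surrogate for gini_split ordering.

    gini_split = (N - S_l/N_l - S_r/N_r)/N with S = sum of squared class
    counts, so minimising it is equivalent to maximising the fraction
    (N_r*S_l + N_l*S_r) / (N_l*N_r). Returned as (numerator, denominator)
    Python ints for overflow-free cross-multiplied comparison.
    """
    nl = int(left.sum())
    nr = int(right.sum())
    sl = int((left.astype(object) ** 2).sum())
    sr = int((right.astype(object) ** 2).sum())
    return nr * sl + nl * sr, nl * nr


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_features,
    n_classes: int,
) -> Optional[tuple[int, float, float]]:
    """Exhaustive best Gini split of a node over the candidate features.

    Parameters
    ----------
    X
        ``(n, M)`` node sample values (full feature width; only candidate
        columns are examined).
    y
        ``(n,)`` integer class codes.
    candidate_features
        Feature indices to consider (a set or array; order irrelevant).

    Returns
    -------
    ``(feature_index, threshold, gini_split)`` of the best valid split, or
    ``None`` when every candidate is constant within the node.
    """
    cands = np.unique(np.asarray(list(candidate_features), dtype=np.int64))
    if cands.size == 0:
        raise ValueError("empty candidate feature set")
    n = X.shape[0]
    if n < 2:
        return None
    Xc = np.ascontiguousarray(X[:, cands])
    order = np.argsort(Xc, axis=0, kind="stable")
    Xs = np.take_along_axis(Xc, order, axis=0)
    valid = Xs[1:] > Xs[:-1]  # (n-1, f): split between i and i+1 allowed
    if not valid.any():
        return None

    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), y] = 1
    # cumulative class counts of the left child for each sorted position
    left = np.cumsum(onehot[order], axis=0)[:-1]  # (n-1, f, c)
    total = onehot.sum(axis=0)  # (c,)
    right = total[None, None, :] - left
    nl = np.arange(1, n, dtype=np.float64)[:, None]
    nr = n - nl
    sl = (left.astype(np.float64) ** 2).sum(axis=2)
    sr = (right.astype(np.float64) ** 2).sum(axis=2)
    score = (n - sl / nl - sr / nr) / n
    score[~valid] = np.inf

    best = score.min()
    # resolve near-ties exactly: float round-off must not override the
    # (gini, feature index, threshold) ordering
    ties = np.argwhere(score <= best + 1e-12)
    best_tuple = None  # (neg exact fraction, feature_index, threshold, i, j)
    best_num = best_den = None
    for i, j in ties:
        num, den = _exact_key(left[i, j], right[i, j])
        thr = 0.5 * (Xs[i, j] + Xs[i + 1, j])
        key = (int(cands[j]), thr)
        if best_tuple is None:
            better = True
        else:
            # larger num/den == smaller gini wins; then lexicographic key
            cross = num * best_den - best_num * den
            better = cross > 0 or (cross == 0 and key < best_tuple)
        if better:
            best_tuple = key
            best_num, best_den = num, den
            best_i, best_j = int(i), int(j)
    feat = int(cands[best_j])
    thr = 0.5 * (Xs[best_i, best_j] + Xs[best_i + 1, best_j])
    return feat, float(thr), float(score[best_i, best_j])


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    sampler: SubspaceSampler,
    n_min: int,
    rng: np.random.Generator,
) -> Tree:
    """Grow an unpruned CART tree on ``(X, y)``.

    ``sampler`` is called once per internal node attempt to produce the
    candidate feature set; ``n_min`` is the minimum node size below or at
    which a node becomes a leaf.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    n_root = X.shape[0]
    tree = Tree(root=None, n_classes=n_classes)  # root filled below

    def make_leaf(counts: np.ndarray) -> LeafNode:
        return LeafNode(
            predicted_class=int(np.argmax(counts)),  # first max = smallest code
            class_counts=counts,
            n_samples=int(counts.sum()),
        )

    def build(idx: np.ndarray) -> Node:
        counts = np.bincount(y[idx], minlength=n_classes)
        n = idx.size
        if n <= n_min or np.count_nonzero(counts) < 2:
            return make_leaf(counts)
        cand = sampler(rng)
        found = best_split(X[idx], y[idx], cand, n_classes)
        if found is None:
            return make_leaf(counts)
        feat, thr, split_score = found
        # clamp float round-off: the chosen split never increases impurity
        decrease = max((n / n_root) * (gini_impurity(counts) - split_score), 0.0)
        tree.feature_decrease[feat] = (
            tree.feature_decrease.get(feat, 0.0) + decrease
        )
        mask = X[idx, feat] <= thr
        return SplitNode(
            feature_index=feat,
            threshold=thr,
            left=build(idx[mask]),
            right=build(idx[~mask]),
            class_counts=counts,
            n_samples=n,
        )

    tree.root = build(np.arange(n_root))
    return tree


def predict_tree(tree: Tree, x: np.ndarray) -> int:
    """Route one sample to a leaf; values equal to a threshold go left."""
    return tree.predict_one(np.asarray(x, dtype=np.float64))
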