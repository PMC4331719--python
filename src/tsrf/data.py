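"""Core labeled-dataset container for genotype and expression matrices.

A :class:`LabeledDataset` holds an ``N x M`` sample-by-feature matrix with a
class label per sample. Genotype matrices carry minor-allele dosage counts in
``{0, 1, 2}``; continuous matrices (e.g. gene expression) carry arbitrary
floats. All downstream stages (screening, tree growth, evaluation) consume
this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

GENOTYPE = "genotype"
CONTINUOUS = "continuous"
_ALLOWED_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class LabeledDataset:
    """Sample x feature matrix with per-sample class labels.

    Parameters
    ----------
    values
        ``(N, M)`` float array; for ``feature_kind="genotype"`` every entry
        must be 0, 1 or 2 (minor-allele dosage). Missing values are rejected.
    feature_ids
        ``M`` unique feature names (e.g. rs numbers, gene symbols).
    sample_ids
        ``N`` unique sample names.
    labels
        ``N`` class labels drawn from a finite set of ``c >= 2`` classes.
    feature_kind
        Either ``"genotype"`` or ``"continuous"``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    feature_kind: str = GENOTYPE
    _label_order: list[str] = field(init=False, repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray([str(y) for y in self.labels], dtype=object)
        self.validate()
        self._label_order = sorted(set(self.labels.tolist()))

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D sample x feature matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_ids) != m:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {m} columns"
            )
        if len(self.labels) != n:
            raise ValidationError(f"{len(self.labels)} labels for {n} samples")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_ids)) != m:
            raise ValidationError("duplicate feature ids")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing/non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r} (missing data is rejected)"
            )
        if self.feature_kind not in (GENOTYPE, CONTINUOUS):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.feature_kind == GENOTYPE:
            bad = ~np.isin(self.values, _ALLOWED_DOSAGES)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"genotype value {self.values[i, j]!r} outside {{0,1,2}} at "
                    f"sample {self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
        classes = set(self.labels.tolist())
        if len(classes) < 2:
            raise ValidationError(
                f"need at least 2 classes, got {sorted(classes)}"
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def label_order(self) -> list[str]:
        """Canonical (sorted) class ordering used for all tie-breaking."""
        return list(self._label_order)

    @property
    def n_classes(self) -> int:
        return len(self._label_order)

    def label_codes(self) -> np.ndarray:
        """Labels encoded as integer indices into :attr:`label_order`."""
        lut = {lab: i for i, lab in enumerate(self._label_order)}
        return np.fromiter((lut[y] for y in self.labels), dtype=np.int64)

    def subset_samples(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            values=self.values[idx],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            feature_kind=self.feature_kind,
        )

    def equals(self, other: "LabeledDataset") -> bool:
        """Field-by-field equality (exact on values)."""
        return (
            self.feature_kind == other.feature_kind
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.labels.tolist() == other.labels.tolist()
            and np.array_equal(self.values, other.values)
        )
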