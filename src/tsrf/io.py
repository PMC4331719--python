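"""Readers and writers for labeled feature matrices.

Two on-disk dialects are supported:

* **tsv** — tab-delimited with a header row; first column is the sample ID,
  one named column carries the class label, every other column is a feature.
* **plink_raw** — whitespace-delimited PLINK ``--recode A`` dosage export with
  header ``FID IID PAT MAT SEX PHENOTYPE SNP1 ...``; the dosage columns are
  the features, ``PHENOTYPE`` 1/2 maps to control/case, and the IID column
  provides the sample ID.

Both readers validate strictly: ragged rows, unparseable numbers, duplicate
IDs, non-{0,1,2} genotype entries and missing values are errors (no
imputation is attempted).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import CONTINUOUS, GENOTYPE, LabeledDataset
from .errors import ParseError, ValidationError

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_PLINK_PHENO = {"1": "control", "2": "case"}

__all__ = ["read_dataset", "write_dataset"]


def _split_lines(path: Path, sep: str | None) -> tuple[list[str], list[list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    rows = [ln.split(sep) if sep else ln.split() for ln in lines]
    header, body = rows[0], rows[1:]
    width = len(header)
    for lineno, row in enumerate(body, start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
    return header, body


def _parse_values(
    body: list[list[str]], cols: list[int], path: Path
) -> np.ndarray:
    out = np.empty((len(body), len(cols)), dtype=np.float64)
    for i, row in enumerate(body):
        for k, j in enumerate(cols):
            try:
                out[i, k] = float(row[j])
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 2}: non-numeric value {row[j]!r} "
                    f"in column {j + 1}"
                ) from None
    return out


def read_dataset(
    path: str | Path,
    format: str = "tsv",
    label_column: str = "label",
    feature_kind: str = "auto",
) -> LabeledDataset:
    """Read a labeled dataset from ``path``.

    Parameters
    ----------
    format
        ``"tsv"`` or ``"plink_raw"`` (see module docstring).
    label_column
        Name of the label column (tsv only; plink_raw uses PHENOTYPE).
    feature_kind
        ``"genotype"``, ``"continuous"``, or ``"auto"`` (genotype iff every
        value lies in {0, 1, 2}). plink_raw is always genotype.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if format == "tsv":
        return _read_tsv(path, label_column, feature_kind)
    if format == "plink_raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path, label_column: str, feature_kind: str) -> LabeledDataset:
    header, body = _split_lines(path, sep="\t")
    if len(header) < 3:
        raise ParseError(
            f"{path}: need at least sample-id, label and one feature column"
        )
    if label_column not in header[1:]:
        raise ParseError(f"{path}: label column {label_column!r} not in header")
    label_idx = header.index(label_column)
    feat_cols = [j for j in range(1, len(header)) if j != label_idx]
    values = _parse_values(body, feat_cols, path)
    if feature_kind == "auto":
        feature_kind = (
            GENOTYPE if np.isin(values, (0.0, 1.0, 2.0)).all() else CONTINUOUS
        )
    return LabeledDataset(
        values=values,
        feature_ids=[header[j] for j in feat_cols],
        sample_ids=[row[0] for row in body],
        labels=np.asarray([row[label_idx] for row in body], dtype=object),
        feature_kind=feature_kind,
    )


def _read_plink_raw(path: Path) -> LabeledDataset:
    header, body = _split_lines(path, sep=None)
    if header[: len(_PLINK_META)] != _PLINK_META:
        raise ParseError(
            f"{path}: header must start with {' '.join(_PLINK_META)}"
        )
    feat_cols = list(range(len(_PLINK_META), len(header)))
    if not feat_cols:
        raise ParseError(f"{path}: no dosage columns after PHENOTYPE")
    labels = []
    for i, row in enumerate(body):
        pheno = row[5]
        if pheno not in _PLINK_PHENO:
            raise ValidationError(
                f"{path}: line {i + 2}: PHENOTYPE must be 1 (control) or 2 "
                f"(case), got {pheno!r}"
            )
        labels.append(_PLINK_PHENO[pheno])
    values = _parse_values(body, feat_cols, path)
    return LabeledDataset(
        values=values,
        feature_ids=[header[j] for j in feat_cols],
        sample_ids=[row[1] for row in body],
        labels=np.asarray(labels, dtype=object),
        feature_kind=GENOTYPE,
    )


def write_dataset(
    d: LabeledDataset,
    path: str | Path,
    format: str = "tsv",
    label_column: str = "label",
) -> None:
    """Write ``d`` as TSV; ``read_dataset`` on the result round-trips exactly.

    Genotype values are written as integers, continuous values with full
    float precision (repr), so a read-back dataset is equal field-by-field.
    """
    if format != "tsv":
        raise ValueError(f"unsupported output format {format!r}")
    if d.n_features == 0:
        raise ValidationError("refusing to write a dataset with no features")
    d.validate()
    if label_column in d.feature_ids or label_column == "sample_id":
        raise ValidationError(
            f"label column name {label_column!r} collides with a feature id"
        )
    path = Path(path)
    genotype = d.feature_kind == GENOTYPE

    def fmt(v: float) -> str:
        return str(int(v)) if genotype else repr(float(v))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["sample_id", label_column] + d.feature_ids) + "\n")
        for i in range(d.n_samples):
            row = [d.sample_ids[i], str(d.labels[i])]
            row.extend(fmt(v) for v in d.values[i])
            fh.write("\t".join(row) + "\n")
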