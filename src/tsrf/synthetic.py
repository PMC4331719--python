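"""Synthetic case-control data with a planted set of informative features.

The genotype generator draws each dosage as ``Binomial(2, p)`` — i.e.
Hardy-Weinberg genotypes at a biallelic locus — with ``p = control_maf``
everywhere except the planted SNPs in cases, where the minor-allele frequency
is shifted upward by ``effect_delta``. This is the minimal model producing the
marginal case-control association structure the two-stage screen is designed
to detect; it deliberately has no linkage disequilibrium, epistasis or
population structure.

A continuous variant (:func:`generate_continuous`) shifts the class mean of
planted features in a standard-normal background, emulating the
expression-matrix setting handled by the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CONTINUOUS, GENOTYPE, LabeledDataset
from .errors import ValidationError

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_case_control",
    "generate_continuous",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated case-control cohort.

    ``control_maf`` is the minor-allele frequency shared by controls and by
    null SNPs in cases; planted SNPs in cases use
    ``control_maf + effect_delta``. For :func:`generate_continuous`,
    ``effect_delta`` is instead the case-minus-control mean shift in SD units
    and ``control_maf`` is ignored.
    """

    n_cases: int = 100
    n_controls: int = 100
    m_features: int = 500
    m_informative: int = 10
    control_maf: float = 0.2
    effect_delta: float = 0.3
    seed: int = 0

    def validate(self, genotype: bool = True) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if not 0 <= self.m_informative <= self.m_features:
            raise ValidationError("m_informative must lie in [0, m_features]")
        if self.effect_delta < 0:
            raise ValidationError("effect_delta must be >= 0")
        if genotype:
            # allele-frequency constraints only bind the genotype model
            if not 0.0 < self.control_maf <= 0.5:
                raise ValidationError("control_maf must lie in (0, 0.5]")
            if self.control_maf + self.effect_delta > 1.0:
                raise ValidationError("control_maf + effect_delta must be <= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated dataset together with the planted (ground-truth) IDs."""

    dataset: LabeledDataset
    informative_ids: frozenset[str]

    @property
    def informative_indices(self) -> np.ndarray:
        ids = self.dataset.feature_ids
        return np.asarray(
            sorted(i for i, f in enumerate(ids) if f in self.informative_ids)
        )


def _ids_and_labels(spec: SyntheticSpec, prefix: str) -> tuple[list, list, np.ndarray]:
    n = spec.n_cases + spec.n_controls
    width = len(str(n))
    sample_ids = [f"case_{i:0{width}d}" for i in range(spec.n_cases)] + [
        f"control_{i:0{width}d}" for i in range(spec.n_controls)
    ]
    labels = np.asarray(
        ["case"] * spec.n_cases + ["control"] * spec.n_controls, dtype=object
    )
    fwidth = len(str(spec.m_features))
    feature_ids = [f"{prefix}{j:0{fwidth}d}" for j in range(spec.m_features)]
    return sample_ids, feature_ids, labels


def generate_case_control(spec: SyntheticSpec) -> SyntheticTruth:
    """Simulate genotype dosages with ``m_informative`` planted SNPs.

    A pure function of ``spec`` — the same spec (including seed) always
    yields a bit-identical dataset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sample_ids, feature_ids, labels = _ids_and_labels(spec, "snp_")
    planted = np.sort(
        rng.choice(spec.m_features, size=spec.m_informative, replace=False)
    )
    p = np.full(
        (spec.n_cases + spec.n_controls, spec.m_features), spec.control_maf
    )
    p[: spec.n_cases, planted] = spec.control_maf + spec.effect_delta
    values = rng.binomial(2, p).astype(np.float64)
    dataset = LabeledDataset(
        values=values,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        labels=labels,
        feature_kind=GENOTYPE,
    )
    return SyntheticTruth(
        dataset=dataset,
        informative_ids=frozenset(feature_ids[j] for j in planted),
    )


def generate_continuous(spec: SyntheticSpec) -> SyntheticTruth:
    """Gaussian class-shift variant: planted features get a case-mean shift
    of ``effect_delta`` standard deviations over a N(0, 1) background."""
    spec.validate(genotype=False)
    rng = np.random.default_rng(spec.seed)
    sample_ids, feature_ids, labels = _ids_and_labels(spec, "gene_")
    planted = np.sort(
        rng.choice(spec.m_features, size=spec.m_informative, replace=False)
    )
    n = spec.n_cases + spec.n_controls
    values = rng.standard_normal((n, spec.m_features))
    values[: spec.n_cases, planted] += spec.effect_delta
    dataset = LabeledDataset(
        values=values,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        labels=labels,
        feature_kind=CONTINUOUS,
    )
    return SyntheticTruth(
        dataset=dataset,
        informative_ids=frozenset(feature_ids[j] for j in planted),
    )
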