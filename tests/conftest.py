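import numpy as np
import pytest

from tsrf import LabeledDataset, SyntheticSpec, generate_case_control


@pytest.fixture
def tiny_genotype() -> LabeledDataset:
    """3 samples x 2 SNPs, two classes."""
    return LabeledDataset(
        values=np.array([[0.0, 2.0], [1.0, 0.0], [2.0, 1.0]]),
        feature_ids=["rs1", "rs2"],
        sample_ids=["s1", "s2", "s3"],
        labels=np.array(["case", "control", "case"], dtype=object),
        feature_kind="genotype",
    )


@pytest.fixture
def separable_dataset() -> LabeledDataset:
    """20 samples, 5 SNPs; feature 0 perfectly separates the classes."""
    rng = np.random.default_rng(7)
    n = 20
    values = rng.integers(0, 3, size=(n, 5)).astype(float)
    labels = np.array(["case"] * (n // 2) + ["control"] * (n // 2), dtype=object)
    values[:, 0] = np.where(labels == "case", 2.0, 0.0)
    return LabeledDataset(
        values=values,
        feature_ids=[f"rs{j}" for j in range(5)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
        feature_kind="genotype",
    )


@pytest.fixture(scope="session")
def small_signal_truth():
    """Small planted-signal cohort shared by model-level tests."""
    return generate_case_control(
        SyntheticSpec(
            n_cases=40,
            n_controls=40,
            m_features=60,
            m_informative=4,
            control_maf=0.2,
            effect_delta=0.45,
            seed=5,
        )
    )
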