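import numpy as np
import pytest

from crowdgene import CVConfig, ExpressionDataset, SyntheticSpec, generate_synthetic_cohort


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 genes x 4 samples, hand-written."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [0.5, 0.5, 2.5, 2.5],
        [9.0, 8.0, 7.0, 6.0],
    ])
    return ExpressionDataset(
        ["TP53", "BCL2", "AARD"], ["s1", "s2", "s3", "s4"],
        values, np.array([1, 1, 0, 0]),
    )


@pytest.fixture
def fast_cv() -> CVConfig:
    return CVConfig(n_folds=3, tree_min_leaf=2, seed=0)


@pytest.fixture
def planted_ds():
    """60 genes x 60 samples with 5 strongly informative genes."""
    spec = SyntheticSpec(n_genes=60, n_samples=60, n_informative=5,
                         effect_size=2.5, seed=11)
    return generate_synthetic_cohort(spec)


def make_perfect_gene_ds(n_noise: int = 9, n_samples: int = 40,
                         seed: int = 5) -> tuple[ExpressionDataset, str]:
    """A dataset whose first gene equals the class label exactly."""
    rng = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n_samples // 2))
    values = rng.normal(size=(n_noise + 1, n_samples))
    values[0] = labels.astype(float)
    genes = ["PERFECT"] + [f"N{i:03d}" for i in range(n_noise)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionDataset(genes, samples, values, labels), "PERFECT"
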