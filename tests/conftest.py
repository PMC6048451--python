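import numpy as np
import pytest

from rewirekit import datagen
from rewirekit.exprio import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """6 genes x 8 samples, fixed values."""
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 8))
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], [f"s{j}" for j in range(8)], values
    )


@pytest.fixture
def rewired_cohort():
    """Two groups of 100 samples: 10-gene block at r = 0.8 vs identity."""
    spec = datagen.RewiringSpec(
        n_genes=10,
        group_sizes=[100, 100],
        corr_matrices=[datagen.block_corr(10, slice(0, 10), 0.8), np.eye(10)],
        seed=42,
    )
    return datagen.generate_rewired_cohort(spec)


@pytest.fixture
def homogeneous_cohort():
    """One homogeneous 20-gene, 60-sample Gaussian cohort."""
    spec = datagen.RewiringSpec(
        n_genes=20, group_sizes=[60], corr_matrices=[np.eye(20)], seed=11
    )
    matrix, _ = datagen.generate_rewired_cohort(spec)
    return matrix
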