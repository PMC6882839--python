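"""Shared fixtures: small planted datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from paretotasks.preprocess import ExpressionMatrix
from paretotasks.synthetic import make_truth, generate_tumors

TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def triangle_cloud():
    """300 points drawn inside the unit triangle (specialist-leaning)."""
    rng = np.random.default_rng(42)
    weights = rng.dirichlet([0.3, 0.3, 0.3], size=300)
    return weights @ TRIANGLE


@pytest.fixture(scope="session")
def small_truth():
    """Planted 3-archetype cohort used across module tests."""
    return make_truth(n_samples=300, n_archetypes=3, n_genes=120,
                      block_size=25, noise_sd=0.1, seed=11)


@pytest.fixture(scope="session")
def small_tumors(small_truth):
    return generate_tumors(small_truth)


@pytest.fixture()
def tiny_expr():
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]],
        index=["s1", "s2", "s3"],
        columns=["g1", "g2"],
    )
    meta = pd.DataFrame(
        {"cancer_type": ["A", "A", "A"],
         "sample_type": ["Primary Tumor", "Primary Tumor", "Metastatic"]},
        index=values.index,
    )
    return ExpressionMatrix(values, meta)
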