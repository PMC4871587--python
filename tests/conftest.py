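import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from somitime import CHICKEN, make_expression_dataset


@pytest.fixture(scope="session")
def chick_dataset():
    """Small chicken-like synthetic dataset with truth, shared across tests."""
    matrix, annotation, truth = make_expression_dataset(
        CHICKEN,
        n_genes=40,
        n_samples=18,
        frac_cyclic=0.5,
        frac_bimodal=0.2,
        amplitude=0.5,
        noise_sd=0.1,
        seed=42,
    )
    return matrix, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
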