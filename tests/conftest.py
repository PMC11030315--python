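"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from muorpred.synthetic import SyntheticConfig, generate_ligands


@pytest.fixture(scope="session")
def small_dataset():
    """150 labeled molecules at the default 3.3:1 imbalance."""
    labeled, _ = generate_ligands(SyntheticConfig(n_labeled=150, seed=42))
    return labeled


@pytest.fixture(scope="session")
def medium_dataset_with_pool():
    """400 labeled molecules + a 300-molecule unlabeled pool."""
    return generate_ligands(SyntheticConfig(n_labeled=400, n_unlabeled=300, seed=7))


@pytest.fixture(scope="session")
def xy_medium(medium_dataset_with_pool):
    labeled, _ = medium_dataset_with_pool
    y = np.array([1 if r.label == "antagonist" else 0 for r in labeled])
    return labeled.smiles(), y
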