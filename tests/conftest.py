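import numpy as np
import pytest

from aneucomp import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort configuration used across unit tests (fast to generate)."""
    return CohortConfig(
        seed=7,
        n_samples_per_type=60,
        n_cancer_types=3,
        n_genes=300,
        n_chromosomes=6,
        planted_aneuploidies=[("CT1", 1, +1, 0.6), ("CT2", 2, -1, 0.6)],
        n_complexes=60,
        n_ppi_edges=800,
        n_pairs_per_case=8,
        n_null_pairs_per_case=8,
        n_negative_pairs_per_case=3,
        n_tfs=10,
        targets_per_tf=20,
        n_degradation_genes=15,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
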