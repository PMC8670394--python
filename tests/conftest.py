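import numpy as np
import pytest

from absflow.datasets import CohortConfig, generate
from absflow.impute import impute_cohort
from absflow.knowledge import load_merged


@pytest.fixture(scope="session")
def merged_kb():
    return load_merged()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared by the slower analysis tests."""
    return generate(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def imputed_cohort(default_cohort):
    return impute_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_block_data(rng, n_rows=60, sizes=(3, 3, 4), rho_in=0.7, rho_out=0.1):
    """Small complete block-correlated sample for unit tests."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    sigma = np.where(labels[:, None] == labels[None, :], rho_in, rho_out)
    np.fill_diagonal(sigma, 1.0)
    chol = np.linalg.cholesky(sigma)
    return rng.standard_normal((n_rows, labels.size)) @ chol.T, labels
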