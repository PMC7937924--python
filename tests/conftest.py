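import numpy as np
import pytest

from stabmark import preprocess, synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec():
    return sd.SyntheticSpec(
        n_samples=60, prevalence=14 / 60, n_genes=150, n_strong=5, n_weak=5, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """(matrix, phenotype, truth) for a 60-sample, 150-gene planted cohort."""
    return sd.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_adjusted(small_cohort):
    mat, pheno, truth = small_cohort
    adj = preprocess.combat_adjust(
        mat, pheno["batch"].to_numpy(), covariates=pheno["outcome"].to_numpy()
    )
    return adj, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
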