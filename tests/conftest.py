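import numpy as np
import pytest

from famburden.burden import BurdenConfig, CohortDataset, run_burden
from famburden.simulate import (
    CohortSimConfig,
    FamilySimConfig,
    simulate_cohort,
    simulate_family,
)


@pytest.fixture(scope="session")
def family_dataset():
    """Small simulated family dataset (300 background sites, fixed seed)."""
    return simulate_family(FamilySimConfig(n_background_variants=300, seed=5))


@pytest.fixture(scope="session")
def cohort_dataset():
    """Default-size simulated cohort (820 cases / 630 controls, fixed seed)."""
    return simulate_cohort(CohortSimConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_as_dataset(cohort_dataset):
    return CohortDataset(
        cohort_dataset["variants"],
        cohort_dataset["annotations"],
        cohort_dataset["genotypes"],
        cohort_dataset["samples"],
        cohort_dataset["covariates"],
    )


@pytest.fixture(scope="session")
def cohort_burden_result(cohort_as_dataset):
    return run_burden(cohort_as_dataset, BurdenConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
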