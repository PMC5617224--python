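import dataclasses

import numpy as np
import pytest

from omicsmr.cohort import SimulationConfig, build_scenario, simulate_genotypes
from omicsmr.mixed_model import EigenKinship, KinshipMatrix


SMALL = SimulationConfig(
    n_individuals=150,
    n_families=25,
    n_snps=1_000,
    n_cpgs=200,
    n_biomarkers=5,
    scenario_counts={
        "SNP_CONFOUNDED": 1,
        "PROTEIN_TO_CPG": 1,
        "CPG_TO_PROTEIN": 1,
        "SMOKING_CONFOUNDED": 1,
        "NULL": 1,
    },
    seed=0,
)


def small_config(**overrides) -> SimulationConfig:
    return dataclasses.replace(SMALL, **overrides)


@pytest.fixture(scope="session")
def small_cohort():
    return build_scenario(SMALL)


@pytest.fixture(scope="session")
def small_genotypes():
    return simulate_genotypes(SMALL)


@pytest.fixture()
def identity_kinship():
    def make(n: int) -> EigenKinship:
        ids = [f"i{i}" for i in range(n)]
        return EigenKinship(KinshipMatrix(0.5 * np.eye(n), ids, source="identity"))

    return make
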