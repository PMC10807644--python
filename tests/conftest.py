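import numpy as np
import pytest

import cuprosage as cp


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with the default effect structure (10 DE panel genes,
    3 signal genes + interaction)."""
    spec = cp.CohortSpec(n_tumor=150, n_normal=50, n_genes=300, seed=11)
    return cp.generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect world: no DE shift, no risk signal."""
    spec = cp.CohortSpec(n_tumor=150, n_normal=50, n_genes=300, de_shift=0.0,
                         effect_sizes=(0.0, 0.0, 0.0), nonlinear_terms=(),
                         background_de_fraction=0.0, clinical_link=0.0, seed=12)
    return cp.generate_cohort(spec)


@pytest.fixture(scope="session")
def drug_world():
    spec = cp.DrugWorldSpec(n_drugs=12, n_targets=60, n_drug_features=40,
                            n_target_features=160, seed=21)
    return cp.generate_drug_world(spec)


@pytest.fixture(scope="session")
def pair_graph(drug_world):
    return cp.build_pair_graph(drug_world, k_features=64, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
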