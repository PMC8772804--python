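import numpy as np
import pandas as pd
import pytest

from gutpipe.containers import AbundanceTable
from gutpipe.synthetic import GeneratorConfig, generate_cohort, default_alphas, default_taxonomy
from gutpipe import taxprofile


@pytest.fixture(scope="session")
def cohort_small():
    """A 120-subject synthetic cohort reused by read-only tests."""
    return generate_cohort(GeneratorConfig(n_subjects=120, fraction_with_v2=0.7, seed=7))


@pytest.fixture(scope="session")
def genus_table(cohort_small):
    rar = taxprofile.rarefy(cohort_small.abundance_v1, 10_000, seed=11)
    return taxprofile.collapse_rank(rar)


@pytest.fixture(scope="session")
def archetype_alphas():
    return default_alphas()


@pytest.fixture(scope="session")
def taxonomy_map():
    tax = default_taxonomy()
    return dict(zip(tax["species_id"], tax["genus"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(rows, samples=None, taxa=None) -> AbundanceTable:
    arr = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=samples, columns=taxa))
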