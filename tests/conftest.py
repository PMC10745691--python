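import numpy as np
import pytest

from gutbrain.core_data import CohortTable, prevalence_filter
from gutbrain.synthetic import SimConfig, simulate_cohort


def make_cohort(records, table, pairing="concurrent", age_window=(0.0, 120.0)):
    """Wrap simulated records + a feature table as an assembled cohort."""
    kwargs = {"max_gap_days": 7.0} if pairing == "concurrent" else {"min_lead_months": 6.0}
    return CohortTable(records, table, age_window, pairing, **kwargs)


@pytest.fixture(scope="session")
def planted_sim():
    """A cohort with one strong planted taxon effect and one positively
    linked gene set; shared across read-only tests."""
    config = SimConfig(
        n_subjects=120,
        n_species=60,
        n_gene_functions=80,
        seed=11,
        planted_taxa=(("Sp_000", 8.0),),
        geneset_link=(("pos_set", 1),),
        covariate_effects=(0.05, 1.0),
        noise_sd=8.0,
    )
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def planted_cohort(planted_sim):
    _, (taxa, genes, records, volumes, gene_sets) = planted_sim
    return make_cohort(records, prevalence_filter(taxa, 0.15))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
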