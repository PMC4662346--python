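import numpy as np
import pandas as pd
import pytest

import provgall as pg


@pytest.fixture(scope="session")
def small_design():
    """Reduced trial: 8 provenances x 2 zones x 1 plot x 3 trees x 4 shoots."""
    return pg.generate_origins(
        8,
        seed=11,
        n_soil_zones=2,
        plots_per_zone_per_provenance=1,
        trees_per_plot_surveyed=3,
        shoots_per_tree=4,
    )


@pytest.fixture(scope="session")
def full_design():
    """Paper-scale design constants (20 provenances, default layout)."""
    return pg.generate_origins(20, seed=1)


@pytest.fixture(scope="session")
def small_genotypes(small_design):
    return pg.simulate_genotypes(
        small_design, n_loci=6, n_ind_per_prov=12, seed=21
    )


@pytest.fixture(scope="session")
def published_summary():
    return pg.datasets.load_gall_survey_summary()


@pytest.fixture(scope="session")
def published_origins():
    return pg.datasets.load_provenance_origins()


@pytest.fixture
def smoke_schedule():
    return pg.MCMCSchedule(n_iter=3_100, burn_in=600, thin=25, seed=5)
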