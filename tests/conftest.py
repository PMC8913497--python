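import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hrd_pharmaco.io_formats import ExpressionMatrix, Unit
from hrd_pharmaco.synthetic import (
    SimulationConfig,
    generate_cell_line_panel,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size simulation used by fast unit tests; keeps the default
    effect sizes but shrinks the matrices."""
    return SimulationConfig(
        seed=7, n_genes=400, n_patients=40, n_cell_lines=60, n_drugs=8,
        n_signature_up=10, n_signature_down=12, n_purity_confounded=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_cell_line_panel(small_config)


@pytest.fixture(scope="session")
def small_status(small_cohort):
    g = small_cohort.genomic_hrd
    return pd.Series(g["status"].to_numpy(), index=g["sample_id"])


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    values = np.round(rng.lognormal(3, 1, (6, 4)))
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], [f"s{i}" for i in range(4)], values, Unit.counts
    )
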