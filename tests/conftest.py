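import numpy as np
import pytest

from mmdrp.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by read-only tests (never mutate)."""
    config = SyntheticConfig(n_cell_lines=40, n_drugs=30, seed=7)
    matrices, catalog, records, truth = generate_cohort(config)
    return {"config": config, "matrices": matrices, "catalog": catalog,
            "records": records, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
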