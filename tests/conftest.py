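import numpy as np
import pytest

from paramask import age_dating, synthetic_data


@pytest.fixture(scope="session")
def taxonomy() -> age_dating.SpeciesTaxonomy:
    return age_dating.SpeciesTaxonomy.from_newick(
        synthetic_data.DEFAULT_TAXONOMY_NEWICK
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_truth():
    """A compact simulated history shared by fixture-hungry tests."""
    params = synthetic_data.SimParams(
        seed=11,
        n_genes=400,
        epoch_events={
            "Eukaryota": 30,
            "Bilateria": 30,
            "Caenorhabditis": 80,
            "Celegans": 40,
        },
    )
    return params, synthetic_data.simulate_history(params)
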