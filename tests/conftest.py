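import numpy as np
import pytest

from pepdemask import (
    BondInventory,
    STUDY_OVERRIDES,
    load_substrate_table,
    reproduce_predictions,
)


@pytest.fixture(scope="session")
def blg_map():
    return load_substrate_table()


@pytest.fixture(scope="session")
def study_inventory(blg_map):
    return BondInventory.from_substrate_map(blg_map, STUDY_OVERRIDES)


@pytest.fixture(scope="session")
def study_result():
    return reproduce_predictions()


@pytest.fixture(scope="session")
def rate_rng():
    return np.random.default_rng(20230725)
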