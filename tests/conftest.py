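import pytest

from rtscreen import pipeline, synthdata
from rtscreen.design import BarcodePool, FactorLevels, build_replicate_layouts


@pytest.fixture(scope="session")
def levels():
    return FactorLevels()


@pytest.fixture(scope="session")
def pool():
    return BarcodePool.random_pool(seed=0)


@pytest.fixture(scope="session")
def screen_layouts(levels, pool):
    """Full default screen: 4 replicates x 2 enzymes = 8 plates."""
    return build_replicate_layouts(levels, pool, n_replicates=4, master_seed=1)


@pytest.fixture(scope="session")
def one_plate(screen_layouts):
    return screen_layouts[0]


@pytest.fixture(scope="session")
def toy_reference():
    return synthdata.build_toy_reference(seed=3)


@pytest.fixture(scope="session")
def response_model():
    return synthdata.ResponseModel()


@pytest.fixture(scope="session")
def small_screen(one_plate, toy_reference, response_model):
    """One simulated plate at shallow depth: (qc table, truth table, demux)."""
    return pipeline.run_synthetic_screen(
        [one_plate], toy_reference, response_model, depth=120, seed=9
    )
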