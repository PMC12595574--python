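import numpy as np
import pytest

from dematelkit import FactorCatalog, analyze
from dematelkit.datasets import load_fpt_motivator_study


@pytest.fixture(scope="session")
def fpt_matrix():
    """The packaged 15-motivator direct-relation matrix."""
    return load_fpt_motivator_study()


@pytest.fixture(scope="session")
def fpt_result(fpt_matrix):
    """Full pipeline result on the packaged study matrix."""
    return analyze(fpt_matrix)


@pytest.fixture
def catalog2():
    return FactorCatalog.from_ids(["P", "Q"])


@pytest.fixture
def catalog4():
    return FactorCatalog.from_pairs(
        [("A", "alpha"), ("B", "beta"), ("C", "gamma"), ("D", "delta")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
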