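import numpy as np
import pytest

from epigene.grid import BinGrid
from epigene.pipeline import run_end_to_end


@pytest.fixture
def grid1000() -> BinGrid:
    """One 1000-bp contig at 200-bp bins: 5 bins."""
    return BinGrid([("chr1", 1000)], bin_width=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_pipeline_result():
    """One full simulate→binarize→train→predict→evaluate run at the default
    study conditions, shared by the calling and acceptance tests."""
    return run_end_to_end()
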