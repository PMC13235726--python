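import numpy as np
import pytest

from lense.config_grid import PipelineConfig
from lense.preprocess import CountMatrix, run_pipeline
from lense.simulate import generate_synthetic_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """200-cell, 500-gene, 3-type synthetic pair with strong signal."""
    return generate_synthetic_scenario(n_cells=200, n_genes=500, seed=1)


@pytest.fixture(scope="session")
def small_counts(small_scenario):
    return small_scenario[0]


@pytest.fixture(scope="session")
def small_result(small_counts):
    cfg = PipelineConfig("lognorm", "all", 5, 0.5)
    return run_pipeline(small_counts, cfg, seed=7)


@pytest.fixture
def tiny_counts():
    """A 4-gene x 3-cell hand-sized matrix for formula checks."""
    counts = np.array(
        [
            [1, 0, 5],
            [3, 2, 0],
            [0, 1, 1],
            [2, 0, 4],
        ]
    )
    return CountMatrix(counts, [f"g{i}" for i in range(4)], [f"c{i}" for i in range(3)])
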