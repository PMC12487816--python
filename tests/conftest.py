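import numpy as np
import pandas as pd
import pytest

from recalde import simulate


@pytest.fixture(scope="session")
def default_truth():
    """One default-parameter synthetic dataset shared across tests."""
    return simulate.generate(simulate.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_truth():
    """A small instance for oracle comparisons (200 genes x 6 tissues)."""
    return simulate.generate(
        simulate.SimulationConfig(seed=3, n_genes=200, n_tissues=6)
    )


@pytest.fixture()
def tiny_matrices():
    """A hand-built 4-gene x 3-tissue pair of matrices with one missing cell."""
    genes = ["g1", "g2", "g3", "g4"]
    tissues = ["t1", "t2", "t3"]
    vg = pd.DataFrame(
        [
            [0.01, 0.012, np.nan],
            [0.04, 0.05, 0.03],
            [0.10, np.nan, 0.09],
            [0.02, 0.02, 0.02],
        ],
        index=genes,
        columns=tissues,
    )
    tpm = pd.DataFrame(
        [
            [50.0, 40.0, 60.0],
            [5.0, 4.0, 6.0],
            [1.0, 0.8, 1.2],
            [20.0, 20.0, 20.0],
        ],
        index=genes,
        columns=tissues,
    )
    return vg, tpm
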