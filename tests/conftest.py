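import numpy as np
import pytest

from scfc.io import ConnectivityMatrix, ModulePartition


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_partition():
    """Six regions in two modules of three."""
    return ModulePartition.from_assignment(
        {"A1": "left", "A2": "left", "A3": "left",
         "B1": "right", "B2": "right", "B3": "right"}
    )


def random_symmetric(n, rng, kind="structural", scale=1.0):
    w = rng.random((n, n)) * scale
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    labels = tuple(f"R{i + 1:02d}" for i in range(n))
    return ConnectivityMatrix(labels, w, kind)


@pytest.fixture
def random_matrix(rng):
    return random_symmetric(8, rng)
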