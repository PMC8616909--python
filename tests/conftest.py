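import logging
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from netfract import Network
from netfract.generators import ring_lattice

logging.getLogger("netfract").setLevel(logging.ERROR)


@pytest.fixture
def path5():
    """Path graph a-b-c-d-e."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def k5():
    nodes = "abcde"
    return Network.from_edges(
        [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    )


@pytest.fixture
def weighted_triangle():
    return Network.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)], weighted=True
    )


@pytest.fixture(scope="session")
def ring1000():
    return ring_lattice(1000, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
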