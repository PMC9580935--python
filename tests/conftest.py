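import numpy as np
import pytest

from straindecon import Metagenotype, simulate


@pytest.fixture
def tiny_mgt() -> Metagenotype:
    """3 samples x 4 sites with hand-picked counts."""
    return Metagenotype(
        samples=np.array(["s1", "s2", "s3"]),
        sites=np.array(["g1", "g2", "g3", "g4"]),
        alt=np.array([[0, 2, 4, 0], [1, 0, 3, 0], [0, 0, 0, 0]]),
        total=np.array([[4, 4, 4, 0], [2, 4, 3, 0], [0, 0, 0, 0]]),
    )


@pytest.fixture
def small_world():
    """A small simulated world shared across tests (deterministic)."""
    return simulate(3, 12, 40, depth=20, seed=7)
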