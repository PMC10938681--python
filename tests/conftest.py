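import numpy as np
import pytest

from patchytissue.geometry import Box
from patchytissue.state import TissueState


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240314)


@pytest.fixture(scope="session")
def lattice_points():
    """2x2x2 cubic lattice in an 80 µm box: every cell a 40 µm cube."""
    g = np.arange(2) * 40.0 + 20.0
    return np.array([[x, y, z] for x in g for y in g for z in g])


@pytest.fixture(scope="session")
def small_tissue():
    """Relaxed-density random 64-cell tissue (1000 µm³ per cell)."""
    r = np.random.default_rng(7)
    L = 40.0
    pos = r.uniform(0, L, (64, 3))
    stiff = r.lognormal(np.log(465) + 0.0484, 0.22, 64)
    return TissueState(pos, stiff, Box(L))
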