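import numpy as np
import pytest

from octmargin import phantom as ph
from octmargin import report as rp
from octmargin.config import PipelineConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shared_model():
    """One depth-adjusted classifier trained from the default training
    phantoms, reused across tests (training is the slow step)."""
    return rp.build_shared_model(PipelineConfig())


@pytest.fixture(scope="session")
def default_phantoms():
    """One phantom per layout template at the default grid."""
    out = {}
    for i, pattern in enumerate(ph.LAYOUT_PATTERNS):
        spec = ph.PhantomSpec(layout_pattern=pattern, seed=40 + i)
        out[pattern] = ph.generate_phantom(spec)
    return out


@pytest.fixture(scope="session")
def small_phantom():
    """A quick-to-render shallow phantom for plumbing tests."""
    spec = ph.PhantomSpec(grid_shape=(48, 48, 60),
                          layout_pattern="infiltrating_boundary", seed=9)
    return ph.generate_phantom(spec)
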