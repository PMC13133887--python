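import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_mask(rng):
    """Seeded random 16^3 mask at density ~0.3."""
    return (rng.random((16, 16, 16)) < 0.3).astype(np.uint8)


@pytest.fixture
def noiseless_phantom():
    from fractacomp.simulate import PhantomSpec, leg_phantom

    return leg_phantom(PhantomSpec(noise_sd=0.0, seed=11))
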