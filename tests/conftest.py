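import numpy as np
import pytest

from alpspipe.schemes import default_scheme
from alpspipe.synthcohort import (
    DiffusivityProfile,
    PhantomGeometry,
    build_phantom,
    simulate_dwi,
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def profile():
    return DiffusivityProfile()


@pytest.fixture(scope="session")
def noiseless_subject(geometry, profile, scheme):
    """Phantom at g = 0.5 with an exact (noise-free) acquisition."""
    comps, labels = build_phantom(geometry, profile, g=0.5)
    dwi = simulate_dwi(comps, scheme, s0=1000.0, noise_sigma=0.0)
    return comps, labels, dwi


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)
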