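import numpy as np
import pytest

from dhikit.gradients import generate_scheme
from dhikit.phantom import default_profiles


@pytest.fixture(scope="session")
def scheme():
    """The reference acquisition: 1 b=0 + 99 directions, max b 3000 s/mm²."""
    return generate_scheme(n_dirs=99, b_max=3000.0, n_b0=1, seed=1)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
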