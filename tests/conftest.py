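import numpy as np
import pytest

from nirpulse import SyntheticConfig, default_forward_matrix


@pytest.fixture
def F():
    return default_forward_matrix()


@pytest.fixture
def default_cfg():
    return SyntheticConfig(seed=0)


def random_invertible_F(rng, max_cond=1e3):
    """Draw a random well-conditioned 2x2 system matrix."""
    while True:
        entries = rng.uniform(-2.0, 2.0, size=(2, 2))
        cond = np.linalg.cond(entries)
        if np.isfinite(cond) and cond < max_cond:
            from nirpulse import SystemMatrix

            return SystemMatrix(entries=entries)
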