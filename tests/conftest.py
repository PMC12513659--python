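import numpy as np
import pytest

from vergebayes import DEFAULT_GEOMETRY, peak_grid

CANONICAL_SIGMAS_DEG = np.arange(0.25, 1.76, 0.25)
CANONICAL_DISTANCES = np.arange(20.0, 101.0, 10.0)


@pytest.fixture(scope="session")
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def full_peak_grid():
    """The canonical 7 noise-levels x 9 distances peak grid at 10^4 trials/cell.

    Computed once per session; shared by the surface-fit and noise-recovery
    checks.
    """
    return peak_grid(
        CANONICAL_SIGMAS_DEG, CANONICAL_DISTANCES, n_trials=10_000, seed=20_250_919
    )
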