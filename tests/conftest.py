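import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from vertomics import MaskVolume, PhantomParams, make_vertebra_phantom


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def malignant_phantom(default_params):
    return make_vertebra_phantom(default_params, "malignant")


@pytest.fixture(scope="session")
def benign_phantom(default_params):
    return make_vertebra_phantom(default_params, "benign_acute")


@pytest.fixture()
def small_mask():
    """An 8x8x8 box mask in a 12x12x12 isotropic grid."""
    arr = np.zeros((12, 12, 12), dtype=bool)
    arr[2:10, 2:10, 2:10] = True
    return MaskVolume(arr, (1.0, 1.0, 1.0))


def random_discretized(seed: int, n_levels: int = 4, max_side: int = 5):
    """A random <=5^3 discretized mask fixture: (levels, mask, n_levels)."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    levels = np.zeros(shape, dtype=int)
    levels[mask] = rng.integers(1, n_levels + 1, size=mask.sum())
    return levels, mask, n_levels
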