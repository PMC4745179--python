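import numpy as np
import pytest

from spikeseg import TFGrid, make_masker, make_song


@pytest.fixture(scope="session")
def grid():
    """Short time-frequency grid used by most unit tests."""
    return TFGrid(duration=0.5)


@pytest.fixture(scope="session")
def full_grid():
    """Full-length (2 s) stimulus grid."""
    return TFGrid(duration=2.0)


@pytest.fixture(scope="session")
def song_pair(grid):
    return make_song(grid, 1, seed=7), make_song(grid, 2, seed=7)


@pytest.fixture(scope="session")
def masker(grid):
    return make_masker(grid, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
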