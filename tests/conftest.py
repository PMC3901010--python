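import warnings

import numpy as np
import pytest

from oigrid import (
    BandParams,
    CellParams,
    WalkParams,
    generate_random_walk,
    simulate,
)


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """The analysis emits RuntimeWarnings on degenerate maps; tests that
    care assert on them explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def walk_60s():
    """One minute of default open-field foraging (seed 0)."""
    return generate_random_walk(WalkParams(), 60.0, seed=0)


@pytest.fixture(scope="session")
def trace_60s(walk_60s):
    """Grid-cell simulation of the one-minute walk with default parameters."""
    return simulate(walk_60s, BandParams(), CellParams())


@pytest.fixture(scope="session")
def walk_600s():
    """Ten minutes of default foraging, enough for field classification."""
    return generate_random_walk(WalkParams(), 600.0, seed=1)


@pytest.fixture(scope="session")
def trace_600s(walk_600s):
    return simulate(walk_600s, BandParams(), CellParams())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
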