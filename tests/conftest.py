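import numpy as np
import pytest

from coevopd import GameParams, LatticeSpec, RunConfig, SimState, WeightParams, init_weights


@pytest.fixture
def tiny_config():
    """A desk-miniature configuration for fast functional tests."""
    return RunConfig(
        lattice=LatticeSpec(L=6),
        game=GameParams(b=1.34),
        weight=WeightParams(delta=0.4, Delta=0.1),
        init_mode="random",
        total_mcs=30,
        measure_window=10,
        replicates=2,
        seed=11,
    )


def uniform_state(L: int, value: int, delta: float = 0.4) -> SimState:
    spec = LatticeSpec(L=L)
    grid = np.full((L, L), value, dtype=np.int8)
    return SimState(spec=spec, strategies=grid, edge_weights=init_weights(spec))


@pytest.fixture
def all_c_state():
    return uniform_state(6, 1)


@pytest.fixture
def all_d_state():
    return uniform_state(6, 0)
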