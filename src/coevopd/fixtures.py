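"""Deterministic tiny states with independently computed expected utilities.

Each fixture bundles a small :class:`~coevopd.model.SimState` with a sidecar
of per-site utilities computed by :func:`brute_force_utility` — a naive
8-term enumeration over Moore offsets with explicit modular arithmetic that
shares no code with the simulation kernel.  Unit tests compare the kernel's
utilities against these sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import COOPERATOR, DEFECTOR, GameParams, LatticeSpec, SimState, WeightParams, init_weights


def brute_force_utility(state: SimState, game: GameParams, row: int, col: int) -> float:
    """Independent 8-term utility oracle: explicit offset loop, symmetric
    weight lookup through the public accessor, textbook payoff table."""
    L = state.spec.L
    s = state.strategies
    u = 0.0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nr, nc = (row + dr) % L, (col + dc) % L
            if s[row, col] == COOPERATOR:
                p = game.R if s[nr, nc] == COOPERATOR else game.S
            else:
                p = game.T if s[nr, nc] == COOPERATOR else game.P
            u += state.weight(row * L + col, nr * L + nc) * p
    return u


@dataclass
class Fixture:
    name: str
    state: SimState
    game: GameParams
    weight: WeightParams
    utilities: np.ndarray  # (L, L) oracle utilities


def _state_from_grid(grid: np.ndarray, weights: np.ndarray | None = None) -> SimState:
    spec = LatticeSpec(L=grid.shape[0])
    w = init_weights(spec) if weights is None else weights
    return SimState(spec=spec, strategies=grid.astype(np.int8), edge_weights=w)


def make_fixture(name: str, b: float = 1.5, delta: float = 0.4) -> Fixture:
    """Build a registered fixture: ``all-C-4x4``, ``all-D-4x4``,
    ``half-plane-4x4``, ``checkerboard-4x4`` or ``random-5x5-seeded``
    (fixed seed 20150; random strategies and random in-range weights)."""
    game = GameParams(b=b)
    wp = WeightParams(delta=delta, Delta=0.1 * delta)
    if name == "all-C-4x4":
        grid = np.full((4, 4), COOPERATOR, dtype=np.int8)
        state = _state_from_grid(grid)
    elif name == "all-D-4x4":
        grid = np.full((4, 4), DEFECTOR, dtype=np.int8)
        state = _state_from_grid(grid)
    elif name == "half-plane-4x4":
        grid = np.zeros((4, 4), dtype=np.int8)
        grid[:, :2] = COOPERATOR
        state = _state_from_grid(grid)
    elif name == "checkerboard-4x4":
        grid = np.indices((4, 4)).sum(axis=0) % 2
        state = _state_from_grid(grid.astype(np.int8))
    elif name == "random-5x5-seeded":
        rng = np.random.default_rng(20150)
        spec = LatticeSpec(L=5)
        grid = rng.integers(0, 2, size=(5, 5), dtype=np.int8)
        weights = rng.uniform(1.0 - delta, 1.0 + delta, size=spec.n_edges)
        state = SimState(spec=spec, strategies=grid, edge_weights=weights)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    L = state.spec.L
    utilities = np.array(
        [[brute_force_utility(state, game, r, c) for c in range(L)] for r in range(L)]
    )
    return Fixture(name=name, state=state, game=game, weight=wp, utilities=utilities)


FIXTURE_NAMES = (
    "all-C-4x4",
    "all-D-4x4",
    "half-plane-4x4",
    "checkerboard-4x4",
    "random-5x5-seeded",
)
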