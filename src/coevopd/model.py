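"""Lattice, parameter and state types for the weighted spatial prisoner's dilemma.

The population lives on an ``L x L`` square lattice with Moore neighborhood
(8 neighbors) and periodic boundary conditions.  Each site holds a strategy
(cooperate or defect) and every undirected lattice edge carries a symmetric
link weight ``w_xy`` confined to ``[1 - delta, 1 + delta]``.

Strategies are encoded as ``int8``: 1 = cooperator (C), 0 = defector (D).

Edge storage: every undirected edge is stored exactly once.  Site ``i`` owns
the four edges toward its E, SE, S and SW neighbors, so the flat weight
array has length ``4 * N`` and the Moore torus edge count ``4 L^2`` falls out
by construction.  The symmetric accessor :meth:`SimState.weight` resolves
either orientation of a pair to the one stored value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COOPERATOR: int = 1
DEFECTOR: int = 0

#: Moore offsets in the fixed neighbor order used everywhere (row, col).
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

#: The four offsets whose edges a site owns (E, SE, S, SW).
_OWNED_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class GameParams:
    """Weak prisoner's dilemma payoffs: T = b > R = 1 > P = 0 >= S = 0.

    ``b`` is the temptation to defect; ``1 < b < 2`` keeps the payoff
    ranking of the dilemma.  ``D = T - P = b`` is the maximal payoff
    difference used to normalize the imitation probability.
    """

    b: float

    R: float = field(default=1.0, init=False)
    P: float = field(default=0.0, init=False)
    S: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not 1.0 < self.b < 2.0:
            raise ValueError(f"temptation must satisfy 1 < b < 2, got b={self.b}")

    @property
    def T(self) -> float:
        return self.b

    @property
    def D(self) -> float:
        """Maximal payoff difference T - P."""
        return self.b - self.P


@dataclass(frozen=True)
class WeightParams:
    """Link-weight dynamics: step ``Delta`` and bound half-width ``delta``.

    Weights are clamped to ``[1 - delta, 1 + delta]``.  ``delta = 0`` or
    ``Delta = 0`` freezes every weight at 1 (the traditional, unweighted
    spatial game).  The amplitude ratio ``Delta/delta`` is defined only for
    ``delta > 0``.
    """

    delta: float
    Delta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"weight bound must satisfy 0 <= delta <= 1, got {self.delta}")
        if self.Delta < 0.0:
            raise ValueError(f"weight step must satisfy Delta >= 0, got {self.Delta}")

    @property
    def ratio(self) -> float:
        """Amplitude ratio Delta/delta; undefined (raises) when delta = 0."""
        if self.delta == 0.0:
            raise ValueError("Delta/delta is undefined when delta = 0")
        return self.Delta / self.delta

    @property
    def frozen(self) -> bool:
        """True when weights can never leave 1 (traditional case)."""
        return self.delta == 0.0 or self.Delta == 0.0

    @classmethod
    def from_ratio(cls, delta: float, ratio: float) -> "WeightParams":
        if delta == 0.0:
            raise ValueError("ratio parameterization requires delta > 0")
        return cls(delta=delta, Delta=ratio * delta)


@dataclass(frozen=True)
class LatticeSpec:
    """Periodic L x L square lattice with Moore neighborhood (k = 8)."""

    L: int

    k: int = field(default=8, init=False)

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValueError(
                f"lattice side must be L >= 3 (neighbor multiplicity collapses below), got L={self.L}"
            )

    @property
    def N(self) -> int:
        return self.L * self.L

    @property
    def n_edges(self) -> int:
        """Undirected Moore-torus edge count, 4 L^2."""
        return 4 * self.N


def build_neighbor_table(spec: LatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor and edge index tables for the periodic Moore lattice.

    Returns
    -------
    neighbors : (N, 8) int32
        ``neighbors[i, k]`` is the flat site index of the k-th Moore
        neighbor of site ``i`` (order given by :data:`MOORE_OFFSETS`),
        with toroidal wraparound.
    edge_index : (N, 8) int32
        ``edge_index[i, k]`` is the index into the flat weight array of the
        undirected edge between ``i`` and its k-th neighbor.  The table is
        symmetric: if ``j = neighbors[i, k]`` and ``i = neighbors[j, m]``
        then ``edge_index[i, k] == edge_index[j, m]``.
    """
    L = spec.L
    rows, cols = np.divmod(np.arange(spec.N, dtype=np.int64), L)
    neighbors = np.empty((spec.N, 8), dtype=np.int32)
    edge_index = np.empty((spec.N, 8), dtype=np.int32)
    owned = {off: d for d, off in enumerate(_OWNED_OFFSETS)}
    for k, (dr, dc) in enumerate(MOORE_OFFSETS):
        nr = (rows + dr) % L
        nc = (cols + dc) % L
        j = nr * L + nc
        neighbors[:, k] = j
        if (dr, dc) in owned:
            edge_index[:, k] = np.arange(spec.N) * 4 + owned[(dr, dc)]
        else:
            # the reverse orientation is owned by the neighbor
            edge_index[:, k] = j * 4 + owned[(-dr, -dc)]
    return neighbors, edge_index


def init_strategies(spec: LatticeSpec, mode: str, rng: np.random.Generator | None = None) -> np.ndarray:
    """Initial strategy grid.

    ``random``: each site independently C or D with probability 1/2.
    ``half_plane``: left half-columns all C, right half all D (even L only);
    the prepared state used for time-course and snapshot experiments.
    """
    L = spec.L
    if mode == "random":
        if rng is None:
            raise ValueError("random initialization requires an rng")
        return rng.integers(0, 2, size=(L, L), dtype=np.int8)
    if mode == "half_plane":
        if L % 2 != 0:
            raise ValueError("half_plane initialization requires even L")
        grid = np.zeros((L, L), dtype=np.int8)
        grid[:, : L // 2] = COOPERATOR
        return grid
    raise ValueError(f"unknown init mode {mode!r} (expected 'random' or 'half_plane')")


def init_weights(
    spec: LatticeSpec,
    wp: WeightParams | None = None,
    mode: str = "uniform",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial flat edge-weight array (length 4 N).

    Default ``uniform``: every weight exactly 1 (the pre-game state).
    ``heterogeneous``: weights drawn uniformly from ``[1 - delta, 1 + delta]``
    — an optional disordered start used only to probe insensitivity of the
    equilibrium to the initial weight distribution; no specific disorder is
    canonical.
    """
    if mode == "uniform":
        return np.ones(spec.n_edges, dtype=np.float64)
    if mode == "heterogeneous":
        if wp is None or rng is None:
            raise ValueError("heterogeneous weights require WeightParams and an rng")
        return rng.uniform(1.0 - wp.delta, 1.0 + wp.delta, size=spec.n_edges)
    raise ValueError(f"unknown weight init mode {mode!r}")


@dataclass
class SimState:
    """Mutable simulation state: strategy grid, edge weights, MCS counter."""

    spec: LatticeSpec
    strategies: np.ndarray  # (L, L) int8, 1=C 0=D
    edge_weights: np.ndarray  # (4N,) float64
    mcs: int = 0

    _neighbors: np.ndarray = field(default=None, repr=False)
    _edge_index: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strategies.shape != (self.spec.L, self.spec.L):
            raise ValueError("strategy grid shape does not match lattice spec")
        if self.edge_weights.shape != (self.spec.n_edges,):
            raise ValueError("weight array length must be 4 L^2")
        if self._neighbors is None:
            nbr, eidx = build_neighbor_table(self.spec)
            object.__setattr__(self, "_neighbors", nbr)
            object.__setattr__(self, "_edge_index", eidx)

    @property
    def neighbors(self) -> np.ndarray:
        return self._neighbors

    @property
    def edge_index(self) -> np.ndarray:
        return self._edge_index

    def site_index(self, row: int, col: int) -> int:
        return (row % self.spec.L) * self.spec.L + (col % self.spec.L)

    def weight(self, x: int, y: int) -> float:
        """Symmetric link-weight accessor: weight(x, y) == weight(y, x)."""
        k = np.flatnonzero(self._neighbors[x] == y)
        if k.size == 0:
            raise ValueError(f"sites {x} and {y} are not neighbors")
        return float(self.edge_weights[self._edge_index[x, k[0]]])

    def set_weight(self, x: int, y: int, value: float) -> None:
        k = np.flatnonzero(self._neighbors[x] == y)
        if k.size == 0:
            raise ValueError(f"sites {x} and {y} are not neighbors")
        self.edge_weights[self._edge_index[x, k[0]]] = value

    def copy(self) -> "SimState":
        return SimState(
            spec=self.spec,
            strategies=self.strategies.copy(),
            edge_weights=self.edge_weights.copy(),
            mcs=self.mcs,
            _neighbors=self._neighbors,
            _edge_index=self._edge_index,
        )


def new_state(
    spec: LatticeSpec,
    init_mode: str = "random",
    rng: np.random.Generator | None = None,
    weight_mode: str = "uniform",
    wp: WeightParams | None = None,
) -> SimState:
    """Construct a fresh state: strategies per ``init_mode``, weights per ``weight_mode``."""
    strategies = init_strategies(spec, init_mode, rng)
    weights = init_weights(spec, wp=wp, mode=weight_mode, rng=rng)
    return SimState(spec=spec, strategies=strategies, edge_weights=weights)
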