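"""The coevolution kernel: payoffs, weighted utilities, weight reinforcement,
strategy imitation, and the asynchronous Monte Carlo schedule.

Two equivalent code paths exist: a pure-Python elementary step
(:func:`elementary_step`) for inspection, fixtures and cross-checks, and a
numba-compiled per-MCS loop (:mod:`coevopd._kernel`) used by :func:`run`.
Both consume randoms via the same contract (see :func:`draw_mcs_randoms`),
so a run is bit-reproducible from its seed on either path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .config import RunConfig
from .model import COOPERATOR, GameParams, SimState, WeightParams, new_state
from .observables import Snapshot, Trajectory, capture_snapshot, cooperation_fraction

K_MOORE = 8


def pairwise_payoff(s_x: int, s_y: int, game: GameParams) -> float:
    """Payoff to the focal player: (C,C)->R=1, (C,D)->S=0, (D,C)->T=b, (D,D)->P=0."""
    if s_x == COOPERATOR:
        return game.R if s_y == COOPERATOR else game.S
    return game.T if s_y == COOPERATOR else game.P


@dataclass(frozen=True)
class UtilityRecord:
    """Accumulated utility of a focal site and its per-neighbor payoffs.

    ``U = sum_k w_xk * P_xk`` over the 8 Moore neighbors (neighbor order as
    in :data:`coevopd.model.MOORE_OFFSETS`); ``avg = U / 8`` is the per-link
    average against which each link's payoff is judged.
    """

    U: float
    avg: float
    payoffs: np.ndarray  # (8,) payoff of the focal player against each neighbor


@dataclass(frozen=True)
class AdoptionDecision:
    W: float
    adopted: bool


def utility(x: int, state: SimState, game: GameParams) -> UtilityRecord:
    """Weighted accumulated utility of site ``x`` (flat index) in the current state."""
    strat = state.strategies.ravel()
    sx = strat[x]
    pay = np.array(
        [pairwise_payoff(sx, strat[y], game) for y in state.neighbors[x]], dtype=np.float64
    )
    w = state.edge_weights[state.edge_index[x]]
    U = float(np.dot(w, pay))
    return UtilityRecord(U=U, avg=U / K_MOORE, payoffs=pay)


def adjust_weights(x: int, record: UtilityRecord, state: SimState, wp: WeightParams) -> SimState:
    """Reward (+Delta) links whose payoff strictly exceeds the focal player's
    average utility, punish (-Delta) the rest (ties punish); clamp to
    ``[1-delta, 1+delta]``.  Mutates the shared edge values in place."""
    if wp.Delta == 0.0:
        return state
    lo, hi = 1.0 - wp.delta, 1.0 + wp.delta
    eidx = state.edge_index[x]
    delta_w = np.where(record.payoffs > record.avg, wp.Delta, -wp.Delta)
    state.edge_weights[eidx] = np.clip(state.edge_weights[eidx] + delta_w, lo, hi)
    return state


def adoption_probability(U_x: float, U_y: float, game: GameParams, k_max: int = K_MOORE) -> float:
    """Probability that x copies y: 0 unless U_y > U_x, else
    ``min(1, (U_y - U_x) / (D * k_max))`` with D = T - P = b.

    Weighted utilities can reach ``8 (1+delta) b`` while the traditional
    normalizer is ``8 b``, so the ratio is clipped at 1.
    """
    if U_y <= U_x:
        return 0.0
    return min(1.0, (U_y - U_x) / (game.D * k_max))


def draw_mcs_randoms(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The frozen randomness contract for one MCS of ``n`` elementary steps.

    Three bulk draws, in this order: focal site indices (uniform over N),
    neighbor picks (uniform over the 8 Moore slots), adoption uniforms.
    The uniform for a step is consumed whether or not an imitation attempt
    happens, so the stream position is state-independent.
    """
    focal = rng.integers(0, n, size=n)
    nbrk = rng.integers(0, K_MOORE, size=n)
    unif = rng.random(n)
    return focal, nbrk, unif


@dataclass(frozen=True)
class StepTrace:
    """Full record of one elementary step, for reproducibility checks."""

    focal: int
    record: UtilityRecord
    neighbor: int
    decision: AdoptionDecision


def elementary_step(
    state: SimState,
    config: RunConfig,
    draws: tuple[int, int, float],
    *,
    utilities_pre_adjust: bool = True,
) -> StepTrace:
    """One asynchronous update (pure-Python reference path).

    ``draws = (focal_site, neighbor_slot, adoption_uniform)``.  Order of
    events: payoffs and utility of the focal player with current weights;
    weight reward/punishment on the focal player's 8 links; imitation of the
    drawn neighbor.  The compared utilities are by default the ones accrued
    under the weights in force when the payoffs were earned (the adjustment
    takes effect from the next interaction); with
    ``utilities_pre_adjust=False`` both utilities are recomputed from the
    post-adjustment weights.  At most the focal site's strategy changes.
    """
    x, k, u = draws
    game, wp = config.game, config.weight
    record = utility(x, state, game)
    y = int(state.neighbors[x, k])

    if utilities_pre_adjust:
        U_x_cmp = record.U
        U_y = utility(y, state, game).U
        adjust_weights(x, record, state, wp)
    else:
        adjust_weights(x, record, state, wp)
        U_x_cmp = float(np.dot(state.edge_weights[state.edge_index[x]], record.payoffs))
        U_y = utility(y, state, game).U

    W = adoption_probability(U_x_cmp, U_y, game)
    adopted = u < W
    if adopted:
        state.strategies.ravel()[x] = state.strategies.ravel()[y]
    return StepTrace(focal=int(x), record=record, neighbor=y, decision=AdoptionDecision(W=W, adopted=bool(adopted)))


def monte_carlo_step(
    state: SimState,
    config: RunConfig,
    rng: np.random.Generator,
    *,
    fast: bool = True,
    utilities_pre_adjust: bool = True,
) -> int:
    """One full MCS: N = L^2 elementary steps with focal players drawn with
    replacement ("each player is selected once on average").  Increments the
    MCS counter; returns the cooperator count."""
    n = state.spec.N
    focal, nbrk, unif = draw_mcs_randoms(rng, n)
    if fast:
        n_coop = _kernel.run_one_mcs(
            state.strategies.ravel(),
            state.edge_weights,
            state.neighbors,
            state.edge_index,
            config.game.b,
            1.0 - config.weight.delta,
            1.0 + config.weight.delta,
            config.weight.Delta,
            not config.weight.frozen,
            utilities_pre_adjust,
            focal,
            nbrk,
            unif,
        )
    else:
        for i in range(n):
            elementary_step(
                state,
                config,
                (int(focal[i]), int(nbrk[i]), float(unif[i])),
                utilities_pre_adjust=utilities_pre_adjust,
            )
        n_coop = int(np.count_nonzero(state.strategies))
    state.mcs += 1
    return int(n_coop)


def run(
    config: RunConfig,
    seed_seq: np.random.SeedSequence | int | None = None,
    *,
    state: SimState | None = None,
    snapshot_steps: tuple[int, ...] = (),
    record_weight_stats: bool = False,
    early_stop: bool = False,
    fast: bool = True,
    utilities_pre_adjust: bool = True,
) -> Trajectory:
    """Run a single realization for ``config.total_mcs`` Monte Carlo steps.

    Records rho_C after every MCS (index 0 is the initial state).  With
    ``early_stop`` the loop ends once the strategy field is uniform (all-C
    and all-D are absorbing for strategies) and rho_C is extended constantly
    to ``total_mcs``; off by default so time courses are unabridged.

    ``seed_seq`` defaults to ``config.seed``; pass the spawned per-replicate
    ``SeedSequence`` when aggregating replicates.
    """
    if seed_seq is None:
        seed_seq = config.seed
    if isinstance(seed_seq, np.random.SeedSequence):
        ss = seed_seq
    else:
        ss = np.random.SeedSequence(int(seed_seq))
    rng = np.random.default_rng(ss)

    if state is None:
        state = new_state(config.lattice, config.init_mode, rng, wp=config.weight)
    n = config.lattice.N

    rho = np.empty(config.total_mcs + 1, dtype=np.float64)
    rho[0] = cooperation_fraction(state)
    mean_w = np.empty_like(rho) if record_weight_stats else None
    var_w = np.empty_like(rho) if record_weight_stats else None
    if record_weight_stats:
        mean_w[0] = np.mean(state.edge_weights)
        var_w[0] = np.var(state.edge_weights)
    snapshots: list[Snapshot] = []
    want_snap = set(snapshot_steps)
    if 0 in want_snap:
        snapshots.append(capture_snapshot(state))

    fixated_at = None
    for t in range(1, config.total_mcs + 1):
        n_coop = monte_carlo_step(
            state, config, rng, fast=fast, utilities_pre_adjust=utilities_pre_adjust
        )
        rho[t] = n_coop / n
        if record_weight_stats:
            mean_w[t] = np.mean(state.edge_weights)
            var_w[t] = np.var(state.edge_weights)
        if t in want_snap:
            snapshots.append(capture_snapshot(state))
        if early_stop and (n_coop == 0 or n_coop == n):
            fixated_at = t
            rho[t + 1 :] = rho[t]
            if record_weight_stats:
                mean_w[t + 1 :] = mean_w[t]
                var_w[t + 1 :] = var_w[t]
            break

    return Trajectory(
        rho=rho,
        mean_weight=mean_w,
        var_weight=var_w,
        snapshots=snapshots,
        seed=int(ss.entropy) if ss.spawn_key == () else None,
        fixated_at=fixated_at,
        final_state=state,
    )
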