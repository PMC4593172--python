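"""Numba inner loop for the asynchronous coevolution dynamics.

One elementary step, in the frozen order:

1. focal player x (pre-drawn) collects its 8 pairwise payoffs and its
   weighted utility ``U_x = sum_k w_xk * P_xk`` with the *current* weights;
2. each of x's links is rewarded (+Delta) when its payoff exceeds the
   per-link average ``U_x / 8``, otherwise punished (-Delta); ties punish
   (the reward condition is strict); weights clamp to ``[1-delta, 1+delta]``;
3. a neighbor y (pre-drawn) is compared: x copies s_y with probability
   ``min(1, (U_y - U_x) / (b * 8))`` when ``U_y > U_x``.

By default the utilities compared in step 3 are the ones accrued in step 1,
i.e. with the weights under which the payoffs were actually earned; the
focal player's weight adjustment takes effect from the next interaction on
(``pre_adjust_utilities=True``).  Passing ``False`` recomputes both
utilities from the post-adjustment weights instead (a sensitivity variant).

Randomness is consumed from three pre-drawn per-MCS arrays (focal sites,
neighbor picks, adoption uniforms); the uniform is consumed unconditionally
so the stream position never depends on the state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _payoff(sx: np.int8, sy: np.int8, b: float) -> float:
    # weak PD: (C,C)->1, (C,D)->0, (D,C)->b, (D,D)->0
    if sx == 1:
        return 1.0 if sy == 1 else 0.0
    return b if sy == 1 else 0.0


@njit(cache=True, inline="always")
def _site_utility(site, strat, weights, neighbors, edge_index, b):
    u = 0.0
    s = strat[site]
    for k in range(8):
        u += weights[edge_index[site, k]] * _payoff(s, strat[neighbors[site, k]], b)
    return u


@njit(cache=True)
def run_one_mcs(
    strat,
    weights,
    neighbors,
    edge_index,
    b,
    lo,
    hi,
    step,
    adjust,
    pre_adjust_utilities,
    focal,
    nbrk,
    unif,
):
    """Advance the state by one MCS (len(focal) elementary steps), in place.

    Returns the cooperator count afterwards.
    """
    pay = np.empty(8, dtype=np.float64)
    norm = b * 8.0
    for i in range(focal.shape[0]):
        x = focal[i]
        sx = strat[x]
        ux = 0.0
        for k in range(8):
            p = _payoff(sx, strat[neighbors[x, k]], b)
            pay[k] = p
            ux += weights[edge_index[x, k]] * p
        avg = ux / 8.0
        y = neighbors[x, nbrk[i]]

        if pre_adjust_utilities:
            ux_cmp = ux
            uy = _site_utility(y, strat, weights, neighbors, edge_index, b)

        if adjust:
            for k in range(8):
                e = edge_index[x, k]
                w = weights[e] + (step if pay[k] > avg else -step)
                if w < lo:
                    w = lo
                elif w > hi:
                    w = hi
                weights[e] = w

        if not pre_adjust_utilities:
            if adjust:
                ux_cmp = 0.0
                for k in range(8):
                    ux_cmp += weights[edge_index[x, k]] * pay[k]
            else:
                ux_cmp = ux
            uy = _site_utility(y, strat, weights, neighbors, edge_index, b)

        if uy > ux_cmp:
            w_prob = (uy - ux_cmp) / norm
            if w_prob > 1.0:
                w_prob = 1.0
            if unif[i] < w_prob:
                strat[x] = strat[y]

    n_coop = 0
    for s in range(strat.shape[0]):
        n_coop += strat[s]
    return n_coop
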