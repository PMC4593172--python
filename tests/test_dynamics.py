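"""Coevolution kernel: payoffs, utilities, weight updates, imitation, schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coevopd as cp
from coevopd.dynamics import draw_mcs_randoms
from coevopd.fixtures import brute_force_utility
from tests.conftest import uniform_state


@pytest.mark.parametrize(
    "s_x, s_y, expected",
    [(1, 1, 1.0), (1, 0, 0.0), (0, 1, 1.34), (0, 0, 0.0)],
)
def test_pairwise_payoffs(s_x, s_y, expected):
    assert cp.pairwise_payoff(s_x, s_y, cp.GameParams(b=1.34)) == expected


class TestUtility:
    def test_all_cooperators_uniform_weights(self, all_c_state):
        rec = cp.utility(0, all_c_state, cp.GameParams(b=1.34))
        assert rec.U == pytest.approx(8.0)
        assert rec.avg == pytest.approx(1.0)

    def test_defector_exploiting_full_neighborhood(self, all_c_state):
        state = all_c_state.copy()
        state.strategies[2, 2] = 0
        rec = cp.utility(state.site_index(2, 2), state, cp.GameParams(b=1.34))
        assert rec.U == pytest.approx(8 * 1.34)

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        """100 random 5x5 states with random in-range weights: the kernel's
        weighted 8-term sum must match an independent offset-loop oracle."""
        game = cp.GameParams(b=1.34)
        rng = np.random.default_rng(42)
        spec = cp.LatticeSpec(L=5)
        for _ in range(100):
            state = cp.SimState(
                spec=spec,
                strategies=rng.integers(0, 2, size=(5, 5), dtype=np.int8),
                edge_weights=rng.uniform(0.6, 1.4, size=spec.n_edges),
            )
            for site in rng.integers(0, spec.N, size=5):
                expected = brute_force_utility(state, game, site // 5, site % 5)
                assert cp.utility(int(site), state, game).U == pytest.approx(
                    expected, rel=1e-12
                )


class TestWeightAdjustment:
    def test_zero_step_leaves_weights_untouched(self, all_c_state):
        game = cp.GameParams(b=1.34)
        wp = cp.WeightParams(delta=0.4, Delta=0.0)
        rec = cp.utility(0, all_c_state, game)
        cp.adjust_weights(0, rec, all_c_state, wp)
        assert (all_c_state.edge_weights == 1.0).all()

    def test_clamped_at_upper_bound(self):
        state = uniform_state(5, 1)
        # three defecting neighbors keep the weighted average below 1
        state.strategies[0, 1] = state.strategies[1, 0] = state.strategies[1, 1] = 0
        game, wp = cp.GameParams(b=1.34), cp.WeightParams(delta=0.4, Delta=0.3)
        x = 0
        state.edge_weights[state.edge_index[x]] = 1.3
        rec = cp.utility(x, state, game)
        assert rec.avg < 1.0
        cp.adjust_weights(x, rec, state, wp)
        w = state.edge_weights[state.edge_index[x]]
        # rewarded cooperator links clamp at 1.4 instead of reaching 1.6
        assert w.max() == pytest.approx(1.4)
        assert w.min() >= 0.6

    def test_tie_punishes_in_uniform_cooperation(self, all_c_state):
        """All payoffs equal the average in an all-C block, so the strict
        reward rule sends every focal edge down by Delta."""
        game, wp = cp.GameParams(b=1.34), cp.WeightParams(delta=0.4, Delta=0.1)
        rec = cp.utility(0, all_c_state, game)
        cp.adjust_weights(0, rec, all_c_state, wp)
        assert np.allclose(all_c_state.edge_weights[all_c_state.edge_index[0]], 0.9)


class TestAdoptionProbability:
    def test_no_adoption_without_strict_advantage(self):
        game = cp.GameParams(b=1.34)
        assert cp.adoption_probability(5.0, 5.0, game) == 0.0
        assert cp.adoption_probability(5.0, 4.0, game) == 0.0

    def test_full_difference_saturates(self):
        game = cp.GameParams(b=1.34)
        assert cp.adoption_probability(0.0, 8 * 1.34, game) == pytest.approx(1.0)

    def test_weighted_utilities_clip_at_one(self):
        # max weighted utility 8*(1+delta)*b exceeds the traditional
        # normalizer 8*b, so the raw ratio 1.8 must clip
        game = cp.GameParams(b=1.5)
        assert cp.adoption_probability(0.0, 8 * 1.8 * 1.5, game) == 1.0

    @settings(max_examples=200, deadline=None)
    @given(
        u_x=st.floats(0.0, 8 * 1.8 * 1.99),
        u_y=st.floats(0.0, 8 * 1.8 * 1.99),
        b=st.floats(1.01, 1.99),
    )
    def test_probability_bounds_under_fuzzing(self, u_x, u_y, b):
        w = cp.adoption_probability(u_x, u_y, cp.GameParams(b=b))
        assert 0.0 <= w <= 1.0


class TestSchedule:
    def test_all_defector_state_is_absorbing(self, tiny_config):
        """With P = S = 0 every utility is 0, so no imitation ever fires."""
        state = uniform_state(6, 0)
        rng = np.random.default_rng(0)
        for _ in range(300):
            cp.monte_carlo_step(state, tiny_config, rng)
        assert (state.strategies == 0).all()

    def test_all_cooperator_strategies_absorb_while_weights_drift(self, tiny_config):
        state = uniform_state(6, 1)
        rng = np.random.default_rng(0)
        for _ in range(300):
            cp.monte_carlo_step(state, tiny_config, rng)
        assert (state.strategies == 1).all()
        # tie punishment drags every edge to the lower clamp
        assert state.edge_weights.min() < 1.0

    def test_frozen_weights_without_step(self):
        cfg = cp.RunConfig(
            lattice=cp.LatticeSpec(L=6),
            game=cp.GameParams(b=1.34),
            weight=cp.WeightParams(delta=0.4, Delta=0.0),
            total_mcs=50,
            measure_window=10,
            seed=4,
        )
        traj = cp.run(cfg)
        assert (traj.final_state.edge_weights == 1.0).all()

    def test_weight_bounds_hold_throughout_run(self):
        cfg = cp.RunConfig(
            lattice=cp.LatticeSpec(L=10),
            game=cp.GameParams(b=1.34),
            weight=cp.WeightParams(delta=0.4, Delta=0.15),
            total_mcs=60,
            measure_window=10,
            seed=9,
        )
        state = cp.new_state(cfg.lattice, "random", np.random.default_rng(9), wp=cfg.weight)
        rng = np.random.default_rng(10)
        for _ in range(cfg.total_mcs):
            cp.monte_carlo_step(state, cfg, rng)
            assert state.edge_weights.min() >= 0.6 - 1e-15
            assert state.edge_weights.max() <= 1.4 + 1e-15

    def test_elementary_step_trace_is_deterministic(self, tiny_config):
        rng = np.random.default_rng(77)
        state0 = cp.new_state(tiny_config.lattice, "random", rng, wp=tiny_config.weight)
        draws = (7, 3, 0.25)
        s1, s2 = state0.copy(), state0.copy()
        t1 = cp.elementary_step(s1, tiny_config, draws)
        t2 = cp.elementary_step(s2, tiny_config, draws)
        assert t1.focal == t2.focal and t1.neighbor == t2.neighbor
        assert t1.decision == t2.decision
        assert np.array_equal(s1.strategies, s2.strategies)
        assert np.array_equal(s1.edge_weights, s2.edge_weights)

    def test_fast_and_reference_paths_agree_exactly(self, tiny_config):
        """The numba kernel and the pure-Python elementary step consume the
        same random stream and must produce bit-identical runs."""
        fast = cp.run(tiny_config, 3, fast=True)
        slow = cp.run(tiny_config, 3, fast=False)
        assert np.array_equal(fast.rho, slow.rho)
        assert np.array_equal(fast.final_state.strategies, slow.final_state.strategies)
        assert np.array_equal(fast.final_state.edge_weights, slow.final_state.edge_weights)

    def test_early_stop_extends_absorbed_trajectory(self):
        cfg = cp.RunConfig(
            lattice=cp.LatticeSpec(L=6),
            game=cp.GameParams(b=1.9),
            weight=cp.WeightParams(delta=0.0, Delta=0.0),
            total_mcs=400,
            measure_window=50,
            seed=2,
        )
        traj = cp.run(cfg, 2, early_stop=True)
        assert traj.fixated_at is not None
        tail = traj.rho[traj.fixated_at :]
        assert (tail == tail[0]).all()
        assert len(traj.rho) == cfg.total_mcs + 1


def _classical_spatial_pd(L, b, total_mcs, seed_seq):
    """Independent classical spatial PD (no weight field at all): payoff-sum
    utilities, proportional imitation normalized by b*8, same RNG contract."""
    spec = cp.LatticeSpec(L=L)
    nbr, _ = cp.build_neighbor_table(spec)
    rng = np.random.default_rng(seed_seq)
    strat = cp.init_strategies(spec, "random", rng).ravel().copy()
    rng.uniform(0.0, 0.0, 0)  # no weight draws in the classical game
    rho = [strat.mean()]

    def payoff_sum(site):
        s = strat[site]
        total = 0.0
        for y in nbr[site]:
            sy = strat[y]
            if s == 1:
                total += 1.0 if sy == 1 else 0.0
            else:
                total += b if sy == 1 else 0.0
        return total

    for _ in range(total_mcs):
        focal, nbrk, unif = draw_mcs_randoms(rng, spec.N)
        for i in range(spec.N):
            x = int(focal[i])
            y = int(nbr[x, int(nbrk[i])])
            ux, uy = payoff_sum(x), payoff_sum(y)
            if uy > ux and unif[i] < min(1.0, (uy - ux) / (b * 8)):
                strat[x] = strat[y]
        rho.append(strat.mean())
    return np.asarray(rho), strat


def test_zero_step_dynamics_trace_identical_to_classical_game():
    """With Delta = 0 the weighted model must replay, draw for draw, an
    independently coded classical spatial PD under a shared seed."""
    cfg = cp.RunConfig(
        lattice=cp.LatticeSpec(L=8),
        game=cp.GameParams(b=1.25),
        weight=cp.WeightParams(delta=0.4, Delta=0.0),
        init_mode="random",
        total_mcs=30,
        measure_window=10,
        seed=123,
    )
    traj = cp.run(cfg)
    rho_ref, strat_ref = _classical_spatial_pd(8, 1.25, 30, 123)
    assert np.array_equal(traj.rho, rho_ref)
    assert np.array_equal(traj.final_state.strategies.ravel(), strat_ref)


def test_classical_cooperation_declines_with_temptation():
    """Traditional-case stationary rho_C is non-increasing in b (within one
    standard error) across a coarse temptation scan."""
    means, sems = [], []
    for b in (1.05, 1.15, 1.25, 1.35):
        vals = []
        for rep in range(5):
            cfg = cp.make_config(
                b, 0.4, 0.0, total_mcs=2000, measure_window=300, L=50, seed=100 + rep
            )
            vals.append(cp.run(cfg, cfg.seed, early_stop=True).stationary(300))
        means.append(np.mean(vals))
        sems.append(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    for i in range(3):
        tol = np.hypot(sems[i], sems[i + 1])
        assert means[i + 1] <= means[i] + tol
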