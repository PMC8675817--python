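"""Receding-horizon prediction, cost, constraint handling and the closed loop."""

import numpy as np
import pytest

from mapmpc.ga_optimizer import GAConfig, ga_optimize, grid_oracle
from mapmpc.mpc_controller import (
    ClosedLoopHistory,
    ControllerState,
    MPCConfig,
    control_step,
    cost,
    extend_reference,
    make_objective,
    move_bounds,
    predict,
    run_closed_loop,
    step_response_matrix,
)
from mapmpc.patient_model import PlantSimulator, simulate


def grid_optimizer(points=41):
    return lambda obj, bounds, rng=None, seeds=None: grid_oracle(obj, bounds, points)


def ga_optimizer(cfg=None):
    cfg = cfg or GAConfig()
    return lambda obj, bounds, rng=None, seeds=None: ga_optimize(
        obj, bounds, cfg, rng=rng, seeds=seeds
    )


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(P=1, M=2), dict(P=0, M=1), dict(u_min=2.0, u_max=2.0),
         dict(mu=-1.0), dict(lam=(0.1, 0.1, 0.1))],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MPCConfig(**kwargs)

    def test_weight_broadcasting(self):
        cfg = MPCConfig(P=3, M=2, mu=2.0, lam=(0.1, 0.3))
        assert np.allclose(cfg.mu_vec, [2, 2, 2])
        assert np.allclose(cfg.lam_vec, [0.1, 0.3])


class TestPredict:
    def test_zero_state_zero_moves_predicts_zero(self, dcanon):
        cfg = MPCConfig()
        p = predict(dcanon, np.zeros(3), np.zeros(63), np.zeros(2), cfg)
        assert np.all(p == 0.0)

    def test_matches_whole_trajectory_simulation(self, dcanon, rng):
        cfg = MPCConfig()
        t = 99  # decision instant: y(t) known, u(t-1) the last applied rate
        u_hist = rng.uniform(0, 2, t)  # u(0..98)
        y_hist = simulate(dcanon, np.concatenate([u_hist, [0.0]]))  # y(0..99)
        past_y = y_hist[::-1][:5]  # y(99), y(98), ...
        past_u = u_hist[::-1][:70]  # u(98), u(97), ...
        moves = rng.uniform(-0.5, 0.5, cfg.M)
        pred = predict(dcanon, past_y, past_u, moves, cfg)
        # oracle: simulate the concatenated input trajectory from time 0
        cum = past_u[0] + np.cumsum(moves)
        u_full = np.concatenate(
            [u_hist, [cum[0]], np.full(dcanon.delay + cfg.P, cum[-1])]
        )
        y_full = simulate(dcanon, u_full)
        oracle = y_full[t + dcanon.delay + 1 : t + dcanon.delay + 1 + cfg.P]
        assert np.allclose(pred, oracle, atol=1e-12)

    def test_unshifted_horizon_inside_dead_time_is_degenerate(self, dcanon, rng):
        # this reachability gap is exactly why the shifted window is the default
        cfg = MPCConfig(P=20, M=2, horizon_shift=False)
        past_u = rng.uniform(0, 2, 70)
        past_y = rng.normal(size=5)
        p1 = predict(dcanon, past_y, past_u, [1.5, -0.5], cfg)
        p2 = predict(dcanon, past_y, past_u, [0.0, 0.0], cfg)
        assert np.allclose(p1, p2, atol=0)

    def test_shifted_horizon_is_reachable(self, dcanon):
        cfg = MPCConfig()
        p1 = predict(dcanon, np.zeros(3), np.zeros(63), [1.0, 0.0], cfg)
        assert np.any(p1 != 0.0)

    def test_wrong_move_count_rejected(self, dcanon):
        with pytest.raises(ValueError):
            predict(dcanon, np.zeros(3), np.zeros(63), [0.1], MPCConfig(M=2))


class TestCost:
    def test_exact_tracking_and_no_moves_costs_nothing(self):
        cfg = MPCConfig(P=4, M=2)
        assert cost(np.ones(4), np.ones(4), np.zeros(2), cfg) == 0.0

    def test_hand_computed_value(self):
        # errors (1, 2) with unit output weights; moves (0.5, 0.5), lambda=0.1:
        # J = 1 + 4 + 0.1 (0.25 + 0.25) = 5.05
        cfg = MPCConfig(P=2, M=2, mu=1.0, lam=0.1)
        J = cost(np.array([2.0, 3.0]), np.array([1.0, 1.0]),
                 np.array([0.5, 0.5]), cfg)
        assert J == pytest.approx(5.05)

    def test_length_mismatch_rejected(self):
        cfg = MPCConfig(P=3, M=2)
        with pytest.raises(ValueError):
            cost(np.ones(2), np.ones(3), np.zeros(2), cfg)

    def test_huge_move_penalty_drives_optimal_moves_to_zero(self, toy_lag_discrete):
        cfg = MPCConfig(P=5, M=2, lam=1e6, u_min=-5, u_max=5, horizon_shift=False)
        state = ControllerState(model=PlantSimulator(toy_lag_discrete))
        obj = make_objective(toy_lag_discrete, state, np.ones(5), cfg)
        res = grid_oracle(obj, move_bounds(cfg, 0.0), 101)
        assert np.allclose(res.best_x, 0.0, atol=0.11)  # one grid cell


class TestControlStep:
    def test_reference_already_met_keeps_the_rate(self, toy_lag_discrete):
        # settle the loop at y=1, u=1/K, then ask for the same reference
        cfg = MPCConfig(P=8, M=2, u_min=0.0, u_max=5.0, horizon_shift=False)
        state = ControllerState(model=PlantSimulator(toy_lag_discrete))
        u_ss = 1.0 / toy_lag_discrete.dc_gain
        for _ in range(300):
            state.model.advance(u_ss)
        state.u_prev = u_ss
        res = control_step(
            toy_lag_discrete, state, np.ones(8), cfg, grid_optimizer(41)
        )
        assert res.u == pytest.approx(u_ss, abs=1e-6)

    def test_matches_exhaustive_grid_oracle(self, dcanon, rng):
        cfg = MPCConfig()
        state = ControllerState(model=PlantSimulator(dcanon))
        for _ in range(30):
            state.u_prev = rng.uniform(0, 2)
            state.model.advance(state.u_prev)
        w = np.ones(cfg.P)
        obj = make_objective(dcanon, state, w, cfg)
        fine = grid_oracle(obj, move_bounds(cfg, state.u_prev), 201)
        res = control_step(dcanon, state, w, cfg, grid_optimizer(201))
        assert res.cost == pytest.approx(fine.best_cost)

    def test_applied_rate_respects_pump_limit(self, dcanon):
        cfg = MPCConfig()
        state = ControllerState(model=PlantSimulator(dcanon))
        res = control_step(
            dcanon, state, 100.0 * np.ones(cfg.P), cfg, grid_optimizer(41)
        )
        assert 0.0 <= res.u <= 2.0

    def test_never_beats_the_zero_move_candidate_backwards(self, dcanon, rng):
        cfg = MPCConfig()
        state = ControllerState(model=PlantSimulator(dcanon))
        res = control_step(
            dcanon, state, np.ones(cfg.P), cfg,
            ga_optimizer(GAConfig(population=20, generations=3)),
            rng=np.random.default_rng(0),
        )
        assert res.cost <= res.zero_move_cost + 1e-12


class TestClosedLoop:
    def test_zero_reference_stays_at_equilibrium(self, dcanon):
        cfg = MPCConfig()
        hist = run_closed_loop(
            dcanon, np.zeros(50), None, cfg, grid_optimizer(21), 50, seed=0
        )
        assert np.all(hist.y == 0.0)
        assert np.all(hist.u == 0.0)

    def test_delay_free_toy_loop_settles_on_the_reference(self, toy_lag_discrete):
        cfg = MPCConfig(P=10, M=2, u_min=0.0, u_max=5.0, horizon_shift=False)
        hist = run_closed_loop(
            toy_lag_discrete, np.ones(60), None, cfg, grid_optimizer(101), 60,
            seed=0,
        )
        assert abs(hist.r[-1] - hist.y[-1]) < 1e-2
        assert np.all(hist.u >= 0.0) and np.all(hist.u <= 5.0)

    def test_same_seed_reproduces_bit_identical_history(self, dcanon):
        cfg = MPCConfig()
        ga = ga_optimizer(GAConfig(population=20, generations=3))
        runs = [
            run_closed_loop(dcanon, np.ones(80), None, cfg, ga, 80, seed=7)
            for _ in range(2)
        ]
        for field in ("r", "y", "u", "d", "cost"):
            a, b = (getattr(h, field) for h in runs)
            assert np.array_equal(a, b)

    def test_history_shapes_and_frame(self, toy_lag_discrete):
        cfg = MPCConfig(P=5, M=1, horizon_shift=False)
        hist = run_closed_loop(
            toy_lag_discrete, np.ones(30), None, cfg, grid_optimizer(31), 30,
            seed=0,
        )
        assert len(hist) == 30
        frame = hist.to_frame()
        assert list(frame.columns) == ["t_s", "r", "u", "y", "d", "map_mmHg"]
        assert len(frame) == 30

    def test_mismatched_sequence_lengths_rejected(self):
        with pytest.raises(ValueError):
            ClosedLoopHistory(
                Ts=1.0, r=np.zeros(3), y=np.zeros(3), u=np.zeros(2),
                d=np.zeros(3), cost=np.zeros(3),
            )


def test_extend_reference_holds_last_value():
    r = extend_reference([0.0, 1.0], 5)
    assert np.allclose(r, [0, 1, 1, 1, 1])
    with pytest.raises(ValueError):
        extend_reference([], 3)


def test_step_response_matrix_first_column_is_plant_step_response(dcanon):
    cfg = MPCConfig()
    G = step_response_matrix(dcanon, cfg)
    # move at t reaches y(t+d+1) with the first delay-free step sample b2
    assert G[0, 0] == pytest.approx(dcanon.num[0])
    # second move lags the first by one sample
    assert np.allclose(G[1:, 1], G[:-1, 0])
    assert G[0, 1] == 0.0
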