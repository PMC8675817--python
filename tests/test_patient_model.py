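"""Patient-model construction, ZOH discretization and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from mapmpc.patient_model import (
    ContinuousPatientModel,
    DiscretePatientModel,
    DisplayMapping,
    InitialHistory,
    PlantSimulator,
    build_continuous_model,
    canonical_model,
    continuous_from_config,
    discretize_zoh,
    simulate,
    step_response,
)


class TestBuildContinuous:
    def test_pole_zero_cancellation_when_t2_equals_t3_and_no_recirculation(self):
        # alpha=0, T2=T3: the numerator lead cancels one denominator factor,
        # leaving a second-order model with poles at -1/T1 and -1/T2
        m = build_continuous_model(K=2.0, T1=4.0, T2=7.0, T3=7.0, alpha=0.0, theta=0.0)
        poles = np.sort(m.poles().real)
        # the double root at -1/7 splits numerically at the sqrt(eps) level
        assert np.allclose(poles, [-1 / 4, -1 / 7, -1 / 7], atol=1e-6)
        # and the numerator zero sits on top of one of them
        assert np.min(np.abs(poles - (-1 / 7))) < 1e-6

    def test_unit_everything_gives_unit_dc_gain(self):
        m = build_continuous_model(K=1.0, T1=1.0, T2=1.0, T3=1.0, alpha=0.0, theta=0.0)
        assert m.dc_gain == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_expansion_matches_convolution_oracle(self, seed):
        r = np.random.default_rng(seed)
        K, T1, T2, T3 = r.uniform(0.5, 50.0, 4)
        alpha = r.uniform(0.0, 0.9)
        m = build_continuous_model(K, T1, T2, T3, alpha, theta=0.0)
        # independent polynomial-multiply oracle
        inner = np.convolve([T3, 1.0], [T2, 1.0])
        inner[-1] -= alpha
        den = np.convolve(inner, [T1, 1.0])
        scale = den[-1]
        assert np.allclose(m.den, den / scale, rtol=1e-12)
        assert np.allclose(m.num, np.array([K * T3, K]) / scale, rtol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(K=1, T1=-1, T2=1, T3=1, alpha=0, theta=0),
            dict(K=1, T1=1, T2=0, T3=1, alpha=0, theta=0),
            dict(K=1, T1=1, T2=1, T3=1, alpha=1.0, theta=0),
            dict(K=1, T1=1, T2=1, T3=1, alpha=0, theta=-5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_continuous_model(**kwargs)


class TestCanonicalModel:
    def test_printed_form(self, canonical):
        assert canonical.dc_gain == pytest.approx(5.0)
        assert canonical.dead_time == 60.0
        assert len(canonical.den) - 1 == 3 and len(canonical.num) - 1 == 1

    def test_asymptotically_stable(self, canonical):
        assert canonical.is_stable
        assert np.all(canonical.poles().real < -1e-3)

    def test_config_roundtrip_defaults_to_canonical(self):
        assert continuous_from_config({}) == canonical_model()
        m = continuous_from_config(
            {"gain": 2.0, "time_constants": [1.0, 2.0, 3.0], "alpha": 0.5,
             "dead_time_s": 10.0}
        )
        assert m.dead_time == 10.0
        assert m.dc_gain == pytest.approx(2.0 / 0.5)


class TestDiscretizeZOH:
    def test_canonical_delay_is_sixty_samples(self, dcanon):
        assert dcanon.delay == 60

    def test_canonical_discrete_model_is_stable(self, dcanon):
        assert dcanon.is_stable

    def test_first_order_lag_matches_closed_form(self):
        T, Ts = 7.0, 0.5
        lag = ContinuousPatientModel(num=(1.0,), den=(T, 1.0))
        d = discretize_zoh(lag, Ts)
        p = np.exp(-Ts / T)
        assert np.allclose(d.den, [1.0, -p], atol=1e-10)
        assert np.allclose(d.num, [1.0 - p], atol=1e-10)

    def test_static_gain_passes_through(self):
        m = ContinuousPatientModel(num=(3.5,), den=(1.0,), dead_time=0.0)
        d = discretize_zoh(m, 1.0)
        assert d.num == (3.5,) and d.den == (1.0,) and d.delay == 0

    def test_fractional_delay_rounds_with_warning(self):
        m = ContinuousPatientModel(num=(1.0,), den=(5.0, 1.0), dead_time=2.4)
        with pytest.warns(UserWarning, match="rounding"):
            d = discretize_zoh(m, 1.0)
        assert d.delay == 2

    @pytest.mark.parametrize("Ts", [0.0, -1.0])
    def test_nonpositive_sampling_time_rejected(self, canonical, Ts):
        with pytest.raises(ValueError):
            discretize_zoh(canonical, Ts)

    @given(
        K=st.floats(0.2, 10.0),
        T1=st.floats(0.5, 40.0),
        T2=st.floats(0.5, 40.0),
        T3=st.floats(0.5, 40.0),
        alpha=st.floats(0.0, 0.9),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_discrete_dc_gain_matches_continuous(self, K, T1, T2, T3, alpha):
        m = build_continuous_model(K, T1, T2, T3, alpha, theta=0.0)
        d = discretize_zoh(m, 1.0)
        assert d.dc_gain == pytest.approx(m.dc_gain, rel=1e-6)


class TestSimulate:
    def test_zero_input_zero_history_gives_zero_output(self, dcanon):
        y = simulate(dcanon, np.zeros(100))
        assert np.all(y == 0.0)

    def test_unit_step_settles_at_the_dc_gain(self, dcanon):
        y = simulate(dcanon, np.ones(3000))
        assert y[-1] == pytest.approx(5.0, abs=1e-3)

    def test_matches_general_linear_filter_oracle(self, dcanon, rng):
        u = rng.normal(0.0, 1.0, 400)
        y = simulate(dcanon, u)
        # independent route: lfilter with the delay folded into the numerator
        b = np.concatenate([np.zeros(dcanon.delay + 1), dcanon.num])
        yref = signal.lfilter(b, dcanon.den, u)
        assert np.allclose(y, yref, atol=1e-10)

    def test_disturbance_is_output_additive(self, dcanon, rng):
        u = rng.uniform(0, 2, 150)
        d = rng.normal(0, 0.2, 150)
        assert np.allclose(
            simulate(dcanon, u, disturbance=d), simulate(dcanon, u) + d
        )

    def test_linearity(self, dcanon, rng):
        u1 = rng.normal(size=200)
        u2 = rng.normal(size=200)
        a, b = 2.5, -1.25
        lhs = simulate(dcanon, a * u1 + b * u2)
        rhs = a * simulate(dcanon, u1) + b * simulate(dcanon, u2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_time_shift_property(self, toy_lag_discrete, rng):
        u = rng.normal(size=100)
        m = 7
        y = simulate(toy_lag_discrete, u)
        y_shift = simulate(toy_lag_discrete, np.concatenate([np.zeros(m), u]))
        assert np.all(y_shift[:m] == 0.0)
        assert np.allclose(y_shift[m:], y, atol=1e-12)

    def test_nonzero_initial_history_continues_a_trajectory(self, dcanon, rng):
        u = rng.uniform(0, 2, 300)
        y_full = simulate(dcanon, u)
        cut = 150
        hist = InitialHistory(
            past_y=y_full[:cut][::-1][:3], past_u=u[:cut][::-1][:63]
        )
        y_tail = simulate(dcanon, u[cut:], history=hist)
        assert np.allclose(y_tail, y_full[cut:], atol=1e-12)

    def test_short_history_rejected(self, dcanon):
        hist = InitialHistory(past_y=np.zeros(1), past_u=np.zeros(5))
        with pytest.raises(ValueError, match="history"):
            simulate(dcanon, np.ones(10), history=hist)


class TestStepResponse:
    def test_dead_time_keeps_output_at_zero(self, dcanon):
        y = step_response(dcanon, 200)
        assert np.all(y[: dcanon.delay + 1] == 0.0)
        assert y[dcanon.delay + 1] != 0.0

    def test_final_value_matches_analytic_dc_gain(self, toy_lag_discrete):
        y = step_response(toy_lag_discrete, 200)
        assert y[-1] == pytest.approx(toy_lag_discrete.dc_gain, rel=1e-6)

    def test_window_must_exceed_delay(self, dcanon):
        with pytest.raises(ValueError):
            step_response(dcanon, 60)


class TestPlantSimulator:
    def test_stepwise_equals_batch_simulation(self, dcanon, rng):
        u = rng.uniform(0, 2, 120)
        y_batch = simulate(dcanon, u)
        sim = PlantSimulator(dcanon)
        y_step = np.array([sim.advance(ui) for ui in u])
        assert np.allclose(y_step, y_batch, atol=1e-12)

    def test_output_is_stable_under_repeated_reads(self, dcanon):
        sim = PlantSimulator(dcanon)
        assert sim.output() == sim.output() == 0.0


class TestDisplayMapping:
    def test_normalized_unit_maps_to_target_pressure(self):
        disp = DisplayMapping()
        assert disp.to_mmhg(0.0) == pytest.approx(40.0)
        assert disp.to_mmhg(1.0) == pytest.approx(80.0)
        assert disp.normalize_amplitude(10.0) == pytest.approx(0.25)
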