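import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpbsim.plant import (
    FlowSensorState,
    InfeasibleSetpointError,
    OverflowModelError,
    PlantParams,
    SensorConfig,
    actuator_step,
    init_flow_sensor,
    make_plant_state,
    occluder_static_flow,
    occluder_static_inverse,
    reservoir_step,
    sense_flow,
    sense_level,
)

# frozen by direct hand substitution: E = exp(0.08*50)-1, then the map
STATIC_FLOW_AT_50 = 1.854514337263189


class TestStaticMap:
    def test_closed_at_zero(self, example_params):
        assert occluder_static_flow(0.0, example_params) == 0.0

    def test_large_opening_limit(self, example_params):
        # algebraic limit is Q0*(1+dR0/R)*R/(R+dR0) = Q0 for K*O' >> 1
        steep = replace(example_params, shape_K=2.0)
        assert occluder_static_flow(100.0, steep) == pytest.approx(5.0, rel=1e-9)

    def test_hand_substitution_oracle(self, example_params):
        assert occluder_static_flow(50.0, example_params) == pytest.approx(
            STATIC_FLOW_AT_50, rel=1e-12
        )

    def test_strictly_increasing_and_bounded(self, example_params):
        grid = np.linspace(0, 100, 1001)
        q = np.array([occluder_static_flow(o, example_params) for o in grid])
        assert np.all(np.diff(q) > 0)
        assert np.all(q < example_params.full_open_flow_Q0)

    def test_out_of_range_opening_rejected(self, example_params):
        with pytest.raises(ValueError):
            occluder_static_flow(-1.0, example_params)
        with pytest.raises(ValueError):
            occluder_static_flow(101.0, example_params)

    def test_overflow_is_explicit(self, example_params):
        hot = replace(example_params, shape_K=8.0)
        with pytest.raises(OverflowModelError):
            occluder_static_flow(100.0, hot)

    @pytest.mark.parametrize("field", [
        "resistance_R", "occluder_resistance_dR0", "full_open_flow_Q0",
        "shape_A", "shape_K", "time_constant_T",
    ])
    def test_positivity_invariants(self, example_params, field):
        with pytest.raises(ValueError, match=field):
            replace(example_params, **{field: 0.0})

    def test_negative_dead_time_rejected(self, example_params):
        with pytest.raises(ValueError):
            replace(example_params, dead_time_L=-0.1)


class TestStaticInverse:
    def test_zero_flow(self, example_params):
        assert occluder_static_inverse(0.0, example_params) == 0.0

    @pytest.mark.parametrize("opening", list(range(5, 100, 5)))
    def test_round_trip(self, example_params, opening):
        q = occluder_static_flow(float(opening), example_params)
        assert occluder_static_inverse(q, example_params) == pytest.approx(
            opening, abs=1e-6
        )

    def test_supremum_infeasible(self, example_params):
        with pytest.raises(InfeasibleSetpointError):
            occluder_static_inverse(example_params.full_open_flow_Q0, example_params)

    def test_negative_flow_rejected(self, example_params):
        with pytest.raises(ValueError):
            occluder_static_inverse(-0.1, example_params)


class TestActuator:
    def test_equilibrium_is_fixed_point(self, example_params):
        state = make_plant_state(example_params, dt=0.01, initial_opening=40.0)
        for _ in range(200):
            state = actuator_step(state, 40.0, 0.01, example_params)
        assert state.effective_opening == pytest.approx(40.0, abs=1e-12)

    def test_fopdt_step_response(self, example_params):
        # step 0 -> 100 with L=0.5, T=2: silent for t < L, 63.2% at t = L+T
        dt = 0.001
        state = make_plant_state(example_params, dt=dt, initial_opening=0.0)
        trace = []
        for i in range(int(3.0 / dt)):
            state = actuator_step(state, 100.0, dt, example_params)
            trace.append(state.effective_opening)
        t = dt * np.arange(1, len(trace) + 1)
        trace = np.array(trace)
        assert np.all(trace[t <= 0.5] == 0.0)
        i_lt = int(round(2.5 / dt)) - 1
        assert trace[i_lt] == pytest.approx(100 * (1 - math.exp(-1)), abs=0.5)

    def test_delay_buffer_length(self, example_params):
        state = make_plant_state(example_params, dt=0.01)
        assert len(state.delay_buffer) == round(example_params.dead_time_L / 0.01)

    def test_dead_time_shields_recent_commands(self, example_params):
        # two runs differing only in commands issued within the last L seconds
        dt = 0.01
        n_recent = round(example_params.dead_time_L / dt) - 1
        rng = np.random.default_rng(3)
        common = rng.uniform(0, 100, 300)

        def run(tail):
            s = make_plant_state(example_params, dt=dt, initial_opening=50.0)
            for u in np.concatenate([common, tail]):
                s = actuator_step(s, u, dt, example_params)
            return s.effective_opening

        assert run(np.full(n_recent, 0.0)) == run(np.full(n_recent, 100.0))

    def test_fine_step_oracle(self, example_params):
        # coarse simulation must match a dt/100 reference integration
        dt = 0.01
        rng = np.random.default_rng(7)
        commands = np.repeat(rng.uniform(0, 100, 40), 50)  # ZOH every 0.5 s

        s = make_plant_state(example_params, dt=dt, initial_opening=20.0)
        for u in commands:
            s = actuator_step(s, u, dt, example_params)

        # independent dense integration of dO'/dt = (u(t - L) - O')/T
        fine = dt / 100
        n_delay = round(example_params.dead_time_L / fine)
        u_fine = np.repeat(commands, 100)
        u_delayed = np.concatenate([np.full(n_delay, 20.0), u_fine])[: u_fine.size]
        o = 20.0
        for u in u_delayed:
            o += fine / example_params.time_constant_T * (u - o)
        assert s.effective_opening == pytest.approx(o, rel=0.005)

    def test_nonpositive_dt_rejected(self, example_params):
        state = make_plant_state(example_params, dt=0.01)
        with pytest.raises(ValueError):
            actuator_step(state, 10.0, 0.0, example_params)


class TestReservoir:
    def test_balance(self):
        v, emptied = reservoir_step(0.45, 4.0, 4.0, 0.0, 0.5)
        assert v == 0.45 and not emptied

    def test_floor_and_flag(self):
        v, emptied = reservoir_step(0.45, 4.0, 5.0, 0.0, 60.0)
        assert v == 0.0 and emptied

    def test_running_sum_oracle(self):
        rng = np.random.default_rng(11)
        q_in = rng.uniform(2, 5, 500)
        q_out = rng.uniform(2, 5, 500)
        d = rng.uniform(0, 0.5, 500)
        dt = 0.01
        v = 5.0  # large enough that the floor never triggers
        for a, b, c in zip(q_in, q_out, d):
            v, emptied = reservoir_step(v, a, b, c, dt)
            assert not emptied
        expected = 5.0 + np.sum(q_in - q_out + d) * dt / 60.0
        assert v == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_flow_rejected(self):
        with pytest.raises(ValueError, match="q_in"):
            reservoir_step(0.45, math.nan, 4.0, 0.0, 0.01)


class TestFlowSensor:
    def test_dc_convergence(self):
        cfg = SensorConfig(flow_noise_sd=0.0)
        st_ = init_flow_sensor(cfg, initial_flow=0.0)
        for _ in range(2000):
            y, st_ = sense_flow(3.0, cfg, st_, dt=0.01)
        assert y == pytest.approx(3.0, abs=1e-6)

    def test_minus_3db_at_cutoff(self):
        cfg = SensorConfig(flow_noise_sd=0.0, lowpass_cutoff=1.0)
        dt = 0.001
        st_ = init_flow_sensor(cfg)
        t = np.arange(0, 20, dt)
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            out[i], st_ = sense_flow(math.sin(2 * math.pi * 1.0 * ti), cfg, st_, dt=dt)
        amp = np.max(np.abs(out[t > 10]))
        assert amp == pytest.approx(1 / math.sqrt(2), abs=0.03)

    def test_seeded_determinism(self):
        cfg = SensorConfig(flow_noise_sd=0.1, seed=42)

        def run():
            s = init_flow_sensor(cfg)
            return [sense_flow(2.0, cfg, s, dt=0.01)[0] for _ in range(100)]

        assert run() == run()

    def test_matches_manual_recursion(self):
        # oracle: the filter is y <- a*y + (1-a)*x with a = exp(-2*pi*fc*dt)
        cfg = SensorConfig(flow_noise_sd=0.0, lowpass_cutoff=2.0)
        rng = np.random.default_rng(5)
        xs = rng.uniform(0, 5, 200)
        s = init_flow_sensor(cfg)
        a = math.exp(-2 * math.pi * 2.0 * 0.01)
        y_ref = 0.0
        for x in xs:
            y, s = sense_flow(x, cfg, s, dt=0.01)
            y_ref = a * y_ref + (1 - a) * x
            assert y == pytest.approx(y_ref, abs=1e-12)


class TestLevelSensor:
    def test_identity(self):
        cfg = SensorConfig(level_noise_sd=0.0, level_quantum=0.0)
        assert sense_level(0.4321, cfg) == 0.4321

    def test_quantization(self):
        cfg = SensorConfig(level_noise_sd=0.0, level_quantum=0.01)
        assert sense_level(0.456, cfg) == pytest.approx(0.46, abs=1e-12)

    def test_seeded_determinism(self):
        cfg = SensorConfig(level_noise_sd=0.01, seed=9)
        assert sense_level(0.45, cfg) == sense_level(0.45, cfg)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            sense_level(-0.1, SensorConfig())


@given(
    flows=st.lists(
        st.tuples(
            st.floats(0, 6, allow_nan=False),
            st.floats(0, 6, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=50,
    )
)
@settings(max_examples=50, deadline=None)
def test_mass_conservation_property(flows):
    """Without floor activation, volume change equals the net-flow integral."""
    v0 = 100.0  # never drains
    v = v0
    net = 0.0
    for q_in, q_out, d in flows:
        v, emptied = reservoir_step(v, q_in, q_out, d, 0.01)
        assert not emptied
        net += (q_in - q_out + d) * 0.01 / 60.0
    assert v - v0 == pytest.approx(net, abs=1e-9)
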