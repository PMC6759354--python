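"""Simulator: spike filtering, greedy spiking rule, voltage dynamics."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from ebnet import build_network, run_simulation
from ebnet.dynamics import (
    SpikeRaster,
    filter_spike_train,
    initial_state,
    instantaneous_rate,
    objective_value,
    spike_delta_objective,
    step,
    voltage_direct,
)
from ebnet.stimuli import constant_pulse


def _raster(events, n=2):
    ns, ts = zip(*events) if events else ((), ())
    return SpikeRaster(np.array(ns, int), np.array(ts, float), n_neurons=n)


class TestFilterSpikeTrain:
    def test_impulse_response_is_decaying_exponential(self):
        tr = filter_spike_train(_raster([(0, 0.0)]), 5.0, 200, 0.1)
        t = np.arange(200) * 0.1
        assert_allclose(tr[0], np.exp(-t / 5.0), rtol=1e-12)
        assert_allclose(tr[1], 0.0)

    def test_empty_raster_gives_zeros(self):
        assert_allclose(filter_spike_train(_raster([]), 5.0, 50, 0.1), 0.0)

    def test_superposition(self):
        both = filter_spike_train(_raster([(0, 1.0), (0, 3.0)]), 7.0, 100, 0.1)
        one = filter_spike_train(_raster([(0, 1.0)]), 7.0, 100, 0.1)
        two = filter_spike_train(_raster([(0, 3.0)]), 7.0, 100, 0.1)
        assert_allclose(both, one + two, atol=1e-12)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            filter_spike_train(_raster([]), -1.0, 10, 0.1)
        with pytest.raises(ValueError):
            filter_spike_train(_raster([(0, 100.0)]), 5.0, 10, 0.1)


class TestVoltageAndObjective:
    def test_perfect_representation_gives_zero_voltage(self, two_neuron_spec):
        V = voltage_direct(two_neuron_spec, [3.0], [3.0], np.zeros(2))
        assert_allclose(V, 0.0)

    def test_direct_evaluation(self):
        spec = build_network([1.0], mu=0.02, tau=25.0, tau_a=1000.0)
        assert_allclose(voltage_direct(spec, [10.0], [0.0], [0.0]), [10 / 1.02])

    def test_cost_free_voltage_independent_of_history(self):
        spec = build_network([1.0, 2.0], mu=0.0, tau=5.0, tau_a=1000.0)
        V1 = voltage_direct(spec, [4.0], [1.0], [0.0, 0.0])
        V2 = voltage_direct(spec, [4.0], [1.0], [9.0, 9.0])
        assert_allclose(V1, V2)

    def test_objective_examples(self, ten_neuron_spec):
        total, err, cost = objective_value(ten_neuron_spec, [3.0], [3.0], np.zeros(10))
        assert total == err == cost == 0.0
        total, err, cost = objective_value(ten_neuron_spec, [10.0], [0.0], np.zeros(10))
        assert_allclose((total, err, cost), (100.0, 100.0, 0.0))
        f = np.zeros(10)
        f[:2] = [1.0, 2.0]
        total, err, cost = objective_value(ten_neuron_spec, [5.0], [5.0], f)
        assert_allclose((total, err, cost), (1.0, 0.0, 1.0))  # 0.2 * (1 + 4)

    def test_objective_terms_nonnegative(self, rng):
        spec = build_network(rng.normal(size=(4, 3)), 0.3, 5.0, 500.0)
        for _ in range(20):
            total, err, cost = objective_value(
                spec, rng.normal(size=3), rng.normal(size=3), rng.uniform(0, 5, 4)
            )
            assert err >= 0 and cost >= 0
            assert_allclose(total, err + cost)


class TestSpikeDeltaObjective:
    def test_matches_normalized_voltage_identity(self, rng):
        """dE expands to (||w_i||^2 + mu)(1 - 2 V_i), so the spiking
        condition dE < 0 is exactly V_i > 1/2."""
        spec = build_network(rng.normal(size=(5, 3)), 0.4, 5.0, 800.0)
        for _ in range(50):
            phi = rng.normal(scale=3, size=3)
            phihat = rng.normal(scale=3, size=3)
            f = rng.uniform(0, 4, 5)
            V = voltage_direct(spec, phi, phihat, f)
            for i in range(5):
                dE = spike_delta_objective(spec, phi, phihat, f[i], i)
                scale = spec.W[i] @ spec.W[i] + spec.mu
                assert_allclose(dE, scale * (1 - 2 * V[i]), rtol=1e-9, atol=1e-9)
                assert (dE < 0) == (V[i] > 0.5)

    def test_boundary_and_above_threshold(self):
        spec = build_network([2.0], mu=0.1, tau=5.0, tau_a=1000.0)
        # choose phi so that V = 1/2 exactly: w*phi = 0.5 / g
        phi_half = 0.5 / (spec.g[0] * 2.0)
        assert_allclose(spike_delta_objective(spec, [phi_half], [0.0], 0.0, 0), 0.0,
                        atol=1e-12)
        phi_06 = 0.6 / (spec.g[0] * 2.0)
        assert spike_delta_objective(spec, [phi_06], [0.0], 0.0, 0) < 0


class TestStep:
    def test_quiescence_is_a_fixed_point(self, two_neuron_spec):
        state = initial_state(two_neuron_spec)
        for _ in range(100):
            j = step(two_neuron_spec, state, np.zeros(1), np.zeros(1), 0.1)
            assert j is None
        assert_allclose(state.V, 0.0)
        assert_allclose(state.r, 0.0)

    def test_spike_from_threshold_lands_at_reset(self):
        """A spike taken at V = 1/2 (+eps) lands at -1/2: the self term
        of the recurrent update is exactly -1 in normalized units."""
        spec = build_network([2.0], mu=0.1, tau=5.0, tau_a=1000.0)
        state = initial_state(spec)
        eps = 1e-9
        phi = np.array([(0.5 + eps) / (spec.g[0] * 2.0)])
        # constant phi, no derivative: closed-form V jumps to 0.5 + eps
        j = step(spec, state, phi, np.zeros(1), 0.1)
        assert j == 0
        V_after = voltage_direct(spec, phi, spec.W.T @ state.r, state.f)
        assert_allclose(V_after[0], -0.5 + eps, atol=1e-6)

    def test_one_spike_per_step_largest_margin_wins(self):
        spec = build_network([1.0, 1.0], mu=0.0, tau=5.0, tau_a=1000.0)
        state = initial_state(spec)
        j = step(spec, state, np.array([10.0]), np.zeros(1), 0.1)
        assert j == 0  # tie broken by lowest index
        assert state.r[0] == 1.0 and state.r[1] == 0.0

    def test_rejects_unknown_spike_rule(self, two_neuron_spec):
        with pytest.raises(ValueError):
            step(two_neuron_spec, initial_state(two_neuron_spec),
                 np.zeros(1), np.zeros(1), 0.1, spike_rule="magic")


class TestRunSimulation:
    def test_zero_stimulus_zero_spikes(self, two_neuron_spec):
        res = run_simulation(two_neuron_spec, constant_pulse(0.0, 100.0))
        assert res.raster.n_spikes == 0
        assert_allclose(res.estimate_trace, 0.0)

    def test_matches_manual_step_loop(self, two_neuron_spec):
        stim = constant_pulse(10.0, 300.0)
        res = run_simulation(two_neuron_spec, stim, record_state=True)
        state = initial_state(two_neuron_spec)
        prev = np.zeros(1)
        events = []
        for k in range(stim.n_samples):
            phi = stim.values[:, k]
            j = step(two_neuron_spec, state, phi, (phi - prev) / 0.1, 0.1)
            prev = phi
            if j is not None:
                events.append(j)
            assert_allclose(state.V, res.V_trace[:, k], atol=1e-12)
        assert events == res.raster.neurons.tolist()

    def test_deterministic_reruns_are_bit_identical(self, ten_neuron_spec, pulse_2s):
        a = run_simulation(ten_neuron_spec, pulse_2s)
        b = run_simulation(ten_neuron_spec, pulse_2s)
        assert np.array_equal(a.raster.neurons, b.raster.neurons)
        assert np.array_equal(a.raster.times, b.raster.times)
        assert np.array_equal(a.estimate_trace, b.estimate_trace)

    def test_objective_trace_is_error_plus_cost(self, two_neuron_spec):
        res = run_simulation(two_neuron_spec, constant_pulse(10.0, 500.0))
        assert_allclose(res.objective_trace, res.error_trace + res.cost_trace)
        assert np.all(res.error_trace >= 0) and np.all(res.cost_trace >= 0)

    def test_isolated_neuron_rate_decays_to_plateau(self):
        """Spike-frequency adaptation: without recurrent input from
        others, the response to a step decays before plateauing."""
        spec = build_network([1.0], mu=1.0, tau=5.0, tau_a=300.0)
        res = run_simulation(spec, constant_pulse(10.0, 1500.0))
        rate = instantaneous_rate(res.raster, res.time.size, 0.1, window_ms=50.0)[0]
        early = rate[1000:2000].mean()   # 100-200 ms
        late = rate[-4000:].mean()       # final 400 ms
        assert early > 1.3 * late
        assert late > 0  # plateau, not silence

    def test_two_neuron_transient_and_delayed_sustained(self, two_neuron_spec, pulse_2s):
        """Strongly excitable neuron responds transiently; the weakly
        excitable one is delayed by inhibition but sustained."""
        res = run_simulation(two_neuron_spec, pulse_2s)
        t0 = res.raster.for_neuron(0)
        t1 = res.raster.for_neuron(1)
        assert t0[0] < 1.0  # immediate response
        assert t1[0] > 20.0  # delayed by recurrent inhibition
        # neuron 0 fires more early, neuron 1 dominates late
        early, late = 400.0, 1600.0
        assert (t0 < early).sum() > (t1 < early).sum()
        assert (t1 > late).sum() > (t0 > late).sum()

    def test_greedy_descent_along_trajectory(self, ten_neuron_spec, pulse_2s):
        res = run_simulation(ten_neuron_spec, pulse_2s)
        assert res.raster.n_spikes > 100
        assert np.all(res.spike_delta_E < 0)

    def test_ei_balance_during_sustained_drive(self, ten_neuron_spec, pulse_2s):
        """Feedforward excitation g_i w_i phi is cancelled by recurrent
        inhibition -g_i w_i phi_hat up to the cost-penalty scale."""
        res = run_simulation(ten_neuron_spec, pulse_2s, record_state=True)
        sl = slice(2000, 20000)
        phi = 10.0
        exc = ten_neuron_spec.g[:, None] * ten_neuron_spec.W * phi
        inh = ten_neuron_spec.g[:, None] * ten_neuron_spec.W * res.estimate_trace[0, sl]
        imbalance = np.abs(exc - inh).mean(axis=1)
        # residual voltage scale is bounded by the threshold scale (1/2)
        # plus the adaptation penalty, well below the raw drive
        assert np.all(imbalance < 0.3 * np.abs(exc).squeeze())

    def test_raster_validation(self):
        with pytest.raises(ValueError):
            SpikeRaster(np.array([0]), np.array([1.0, 2.0]), n_neurons=2)
        with pytest.raises(ValueError):
            SpikeRaster(np.array([0, 0]), np.array([2.0, 1.0]), n_neurons=1)
        with pytest.raises(ValueError):
            SpikeRaster(np.array([5]), np.array([1.0]), n_neurons=2)
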