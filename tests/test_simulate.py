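"""Integrators, input protocols, paired trials, reproducibility."""

import numpy as np
import pytest

from contractrnn import (
    DivergenceError,
    NetworkState,
    NeuralModelSpec,
    Perturbation,
    SimulationProtocol,
    generate_sinusoid_inputs,
    integrate,
    integrate_ode,
    run_trial_pair,
)
from contractrnn import fixtures


class TestIntegrateODE:
    def test_scalar_exponential_decay(self):
        times, traj = integrate_ode(
            lambda t, z: -z, np.array([1.0]), t_end=5.0, dt=1e-3
        )
        np.testing.assert_allclose(traj[:, 0], np.exp(-times), atol=1e-6)

    def test_counterexample_matches_closed_form(self):
        a_of_t, x_closed, y_closed = fixtures.counterexample_system()
        times, traj = integrate_ode(
            lambda t, z: a_of_t(t) @ z, np.array([0.0, 1.0]), t_end=2.0, dt=1e-4
        )
        assert abs(traj[-1, 0] - np.sinh(2.0)) <= 1e-4
        np.testing.assert_allclose(traj[:, 1], y_closed(times), atol=1e-6)

    def test_divergence_reports_blowup_time(self):
        with pytest.raises(DivergenceError) as err:
            integrate_ode(lambda t, z: z**2, np.array([10.0]), t_end=5.0, dt=1e-2)
        assert 0 < err.value.t <= 5.0


class TestSinusoidInputs:
    def test_sampled_ranges(self):
        spec = generate_sinusoid_inputs(200, dt=1e-2, seed=0)
        assert np.all((spec.amplitudes >= 0) & (spec.amplitudes <= 20))
        assert np.all((spec.frequencies >= 1e-2) & (spec.frequencies <= 1.0))
        assert np.all((spec.phases >= 0) & (spec.phases <= 2 * np.pi))

    def test_deterministic_from_seed(self):
        a = generate_sinusoid_inputs(10, 1e-2, seed=42)
        b = generate_sinusoid_inputs(10, 1e-2, seed=42)
        grid = np.linspace(0, 10, 101)
        for t in grid:
            np.testing.assert_array_equal(a(t), b(t))

    def test_amplitude_bound_pointwise(self):
        spec = generate_sinusoid_inputs(10, 1e-2, seed=1)
        for t in np.linspace(0, 50, 500):
            assert np.all(np.abs(spec(t)) <= spec.amplitudes + 1e-12)

    def test_physical_frequency_override(self):
        spec = generate_sinusoid_inputs(50, 1e-2, seed=0, freq_range=(1.0, 5.0))
        assert np.all((spec.frequencies >= 1.0) & (spec.frequencies <= 5.0))


class TestIntegrate:
    def test_plastic_run_shapes_and_layout(self):
        model, plast, state = fixtures.random_plastic_network(n=4, seed=0)
        proto = SimulationProtocol(t_end=1.0, dt=1e-2, seed=0)
        res = integrate(model, plast, proto, state)
        assert res.states.shape == (101, 4 + 16)
        np.testing.assert_array_equal(res.x[0], state.x)
        np.testing.assert_array_equal(res.w[0], state.w)

    def test_static_run_freezes_weights(self):
        model, _, state = fixtures.sparse_static_network(6, 2, 0.1, seed=0)
        proto = SimulationProtocol(t_end=1.0, dt=1e-2, seed=0)
        res = integrate(model, None, proto, state)
        assert res.states.shape == (101, 6)
        np.testing.assert_array_equal(res.w[-1], state.w)

    def test_euler_maruyama_with_vanishing_sigma_is_forward_euler(self):
        model, plast, state = fixtures.random_plastic_network(n=3, seed=2)
        proto_noise = SimulationProtocol(t_end=0.5, dt=1e-2, seed=2, noise_sigma=1e-300)
        res_em = integrate(model, plast, proto_noise, state)
        # forward Euler reference on the same RHS
        from contractrnn.dynamics import combined_rhs

        z = state.flatten()
        for step in range(50):
            s = NetworkState.unflatten(z, 3)
            z = z + 1e-2 * combined_rhs(s, model, plast, np.zeros(3), step * 1e-2)
        np.testing.assert_allclose(res_em.states[-1], z, rtol=1e-12)

    def test_noise_enters_neural_coordinates_only(self):
        model, plast, state = fixtures.random_plastic_network(n=3, seed=3)
        proto0 = SimulationProtocol(t_end=0.1, dt=1e-2, seed=3, noise_sigma=0.0)
        protoN = SimulationProtocol(t_end=0.1, dt=1e-2, seed=3, noise_sigma=0.2)
        # one Euler step from identical states: weight update identical, neural differs
        integrate(model, plast, proto0, state)
        resN = integrate(model, plast, protoN, state)
        # weight coordinates after the first EM step depend only on the drift
        from contractrnn.dynamics import combined_rhs

        drift = combined_rhs(state, model, plast, np.zeros(3), 0.0)
        expected_w = state.flatten()[3:] + 1e-2 * drift[3:]
        np.testing.assert_allclose(resN.states[1][3:], expected_w, rtol=1e-12)
        assert not np.allclose(resN.states[1][:3], state.x + 1e-2 * drift[:3])

    def test_perturbation_window_midpoint(self):
        proto = SimulationProtocol(
            t_end=10.0, dt=1e-2, seed=0, perturbation=Perturbation(duration_steps=100)
        )
        assert proto.perturbation_window() == (5.0, 6.0)

    def test_bitwise_reproducibility(self):
        model, plast, state = fixtures.random_plastic_network(n=5, seed=7)
        inp = generate_sinusoid_inputs(5, 1e-2, seed=7)
        proto = SimulationProtocol(t_end=2.0, dt=1e-2, seed=7, input=inp)
        a = integrate(model, plast, proto, state)
        b = integrate(model, plast, proto, state)
        assert np.array_equal(a.states, b.states)

    def test_halving_dt_barely_changes_certified_run(self):
        model, plast, state = fixtures.random_plastic_network(n=5, seed=7)
        inp = generate_sinusoid_inputs(5, 1e-2, seed=7)
        res1 = integrate(
            model, plast, SimulationProtocol(t_end=5.0, dt=1e-2, seed=7, input=inp), state
        )
        res2 = integrate(
            model, plast, SimulationProtocol(t_end=5.0, dt=5e-3, seed=7, input=inp), state
        )
        rel = np.linalg.norm(res1.states[-1] - res2.states[-1]) / np.linalg.norm(
            res1.states[-1]
        )
        assert rel < 1e-4


class TestRunTrialPair:
    def test_contracting_fixture_pairs_converge(self):
        model, plast, _ = fixtures.random_plastic_network(n=10, seed=0)
        proto = SimulationProtocol(
            t_end=20.0, dt=1e-2, seed=0, input=generate_sinusoid_inputs(10, 1e-2, 0)
        )
        summary = run_trial_pair(model, plast, proto, n_pairs=2)
        d = summary.mean_distance
        assert d[-1] < 1e-3 * d[0]

    def test_pulse_separates_then_reconverges(self):
        model, plast, _ = fixtures.random_plastic_network(n=10, seed=1)
        proto = SimulationProtocol(
            t_end=20.0,
            dt=1e-2,
            seed=1,
            input=generate_sinusoid_inputs(10, 1e-2, 1),
            perturbation=Perturbation(value=10.0, duration_steps=100),
        )
        summary = run_trial_pair(model, plast, proto, n_pairs=1, perturb_one=True)
        d, t = summary.mean_distance, summary.times
        window = proto.perturbation_window()
        in_pulse = (t >= window[0]) & (t < window[1])
        assert d[in_pulse].max() > 10 * d[t < window[0]][-1]  # pulse separates
        assert d[-1] < d[t < window[0]].max()  # final below pre-pulse peak

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            SimulationProtocol(t_end=1.0, dt=-1e-2)
        model, plast, _ = fixtures.random_plastic_network(n=4, seed=0)
        with pytest.raises(ValueError):
            run_trial_pair(model, plast, SimulationProtocol(t_end=1.0), n_pairs=0)
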