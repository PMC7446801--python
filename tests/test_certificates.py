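"""Stability certificates: hypotheses, margins, and their simulated consequences."""

import json

import numpy as np
import pytest

from contractrnn import (
    EIPartition,
    Metric,
    NeuralModelSpec,
    NetworkState,
    PlasticitySpec,
    SparsityProfile,
    check_plasticity_hypotheses,
    combined_jacobian,
    ei_balance_certificate,
    eigenvalue_test_insufficiency_demo,
    esn_discrete_contraction_check,
    hebbian_contraction_certificate,
    hebbian_metric,
    mu2,
    mu2_combined_in_k_metric,
    sparsity_certificate,
    static_symmetric_part_certificate,
)
from contractrnn import fixtures


class TestPlasticityHypotheses:
    def test_equal_learning_rates_pass(self):
        # all-ones K is rank-1 PSD, symmetric, entrywise positive
        rep = check_plasticity_hypotheses(PlasticitySpec.uniform(4, k=1.0))
        assert rep.passed and not rep.failed_assumptions()

    def test_indefinite_k_fails(self):
        rep = check_plasticity_hypotheses(
            PlasticitySpec(np.array([[1.0, 2.0], [2.0, 1.0]]))
        )
        assert not rep.passed
        assert "k_positive_semidefinite" in rep.failed_assumptions()

    def test_negative_entry_fails(self):
        rep = check_plasticity_hypotheses(
            PlasticitySpec(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        )
        assert not rep.passed
        assert "k_entrywise_positive" in rep.failed_assumptions()

    def test_asymmetric_k_fails(self):
        rep = check_plasticity_hypotheses(
            PlasticitySpec(np.array([[1.0, 0.5], [0.4, 1.0]]))
        )
        assert "k_symmetric" in rep.failed_assumptions()


class TestHebbianCertificate:
    def test_two_neuron_uniform_plasticity_certifies(self):
        model, plast, _ = fixtures.random_plastic_network(n=2, seed=1)
        rep = hebbian_contraction_certificate(model, plast)
        assert rep.passed
        assert rep.details["max_tail_mu2"] < 0
        assert np.all(rep.margins > 0)

    def test_failing_k_is_named(self):
        model = NeuralModelSpec(n=2)
        rep = hebbian_contraction_certificate(
            model, PlasticitySpec(np.array([[1.0, 2.0], [2.0, 1.0]]))
        )
        assert not rep.passed
        assert "k_positive_semidefinite" in rep.failed_assumptions()

    def test_no_forgetting_fails(self):
        # gamma = 0 removes the -gamma I negativity of the weight block
        model, plast, _ = fixtures.random_plastic_network(n=2, seed=1, gamma=0.0)
        rep = hebbian_contraction_certificate(model, plast)
        assert not rep.passed
        assert "gamma_positive" in rep.failed_assumptions()

    def test_nonidentity_activation_rejected_as_hypothesis(self):
        model = NeuralModelSpec(n=2, activation="tanh")
        rep = hebbian_contraction_certificate(model, PlasticitySpec.uniform(2))
        assert not rep.passed
        assert "identity_activation" in rep.failed_assumptions()

    def test_metric_scales_synaptic_coordinates(self):
        plast = PlasticitySpec(np.array([[1.0, 4.0], [4.0, 16.0]]) + 1e-9)
        theta = hebbian_metric(plast).theta
        diag = np.diag(theta)
        np.testing.assert_allclose(diag[:2], 1.0)
        np.testing.assert_allclose(
            diag[2:], (1.0 / np.sqrt(plast.k_matrix)).ravel()
        )

    def test_matrix_free_mu2_matches_dense_transform(self):
        # dual route: structured matvec vs explicit theta J theta^{-1}
        rng = np.random.default_rng(6)
        n = 4
        model = NeuralModelSpec(n=n)
        k = rng.uniform(0.3, 2.0, (n, n))
        plast = PlasticitySpec(0.5 * (k + k.T), gamma=0.7)
        state = NetworkState(rng.uniform(-1, 1, n), rng.uniform(-1, 1, (n, n)))
        dense = mu2_combined_in_k_metric(state, model, plast, dense_threshold=900)
        matfree = mu2_combined_in_k_metric(state, model, plast, dense_threshold=1)
        assert dense == pytest.approx(matfree, abs=1e-7)


class TestSparsityCertificate:
    def test_hand_computed_margins(self):
        model = NeuralModelSpec(n=1, activation="tanh", beta=1.0)
        prof = SparsityProfile([1], [0.5], w_max=0.1)
        rep = sparsity_certificate(model, prof)
        assert rep.margins[0] == pytest.approx(0.4, abs=1e-12)
        assert rep.passed
        rep2 = sparsity_certificate(
            model, SparsityProfile([2], [0.5], w_max=0.1)
        )
        assert rep2.margins[0] == pytest.approx(-0.2, abs=1e-12)
        assert not rep2.passed

    def test_disconnected_network_trivially_passes(self):
        model = NeuralModelSpec(n=3, beta=1.0)
        rep = sparsity_certificate(
            model, SparsityProfile(np.zeros(3), np.zeros(3), w_max=5.0)
        )
        assert rep.passed
        np.testing.assert_allclose(rep.margins, model.beta_per_neuron)

    def test_plastic_synapses_require_bounded_activation(self):
        model = NeuralModelSpec(n=1, activation="identity")
        with pytest.raises(ValueError, match="bounded activation"):
            sparsity_certificate(model, SparsityProfile([1], [0.5], w_max=0.1))

    def test_margin_monotonicity(self):
        model = NeuralModelSpec(n=1, activation="tanh", beta=1.0)

        def margin(p, w_max, alpha):
            return sparsity_certificate(
                model, SparsityProfile([p], [alpha], w_max)
            ).margins[0]

        margins_in_p = [margin(p, 0.1, 0.2) for p in range(6)]
        assert np.all(np.diff(margins_in_p) < 0)
        # affine in p with slope -(g_max w_max + alpha r_max)
        np.testing.assert_allclose(
            np.diff(margins_in_p), -(1.0 * 0.1 + 0.2 * 1.0), rtol=1e-12
        )
        assert margin(2, 0.3, 0.2) < margin(2, 0.1, 0.2)
        assert margin(2, 0.1, 0.5) < margin(2, 0.1, 0.2)
        big_beta = NeuralModelSpec(n=1, activation="tanh", beta=3.0)
        assert (
            sparsity_certificate(
                big_beta, SparsityProfile([2], [0.2], 0.1)
            ).margins[0]
            > margin(2, 0.1, 0.2)
        )


class TestStaticSymmetricPart:
    def test_antisymmetric_weights_pass_with_full_margin(self):
        model = NeuralModelSpec(n=2, beta=1.0)
        rep = static_symmetric_part_certificate([[0.0, 3.0], [-3.0, 0.0]], model)
        assert rep.passed and rep.margin == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "w, margin, passed", [(0.5, 0.5, True), (2.0, -1.0, False)]
    )
    def test_two_neuron_cancellation(self, w, margin, passed):
        model, state = fixtures.two_neuron_ei(w)
        rep = static_symmetric_part_certificate(state.w, model)
        assert rep.margin == pytest.approx(margin, abs=1e-12)
        assert rep.passed is passed


class TestEIBalance:
    def test_exact_balance_invariant_to_cross_amplitude(self):
        margins = []
        for scale in (1.0, 10.0, 100.0):
            model, part, state = fixtures.ei_population_network(
                8, 8, cross_scale=scale, seed=0
            )
            rep = ei_balance_certificate(state.w, part, model)
            assert rep.passed
            margins.append(rep.margin)
        assert max(margins) - min(margins) < 1e-10

    def test_positive_feedback_fails(self):
        model, part, state = fixtures.ei_population_network(8, 8, seed=0)
        w = np.array(state.w)
        e, i = part.excitatory, part.inhibitory
        # flip the I->E block: large-amplitude positive feedback
        w[np.ix_(e, i)] = 20.0 * np.abs(w[np.ix_(e, i)])
        rep = ei_balance_certificate(w, part, model)
        assert not rep.passed

    def test_single_pair_consistent_with_symmetric_part_test(self):
        model, state = fixtures.two_neuron_ei(0.5)
        part = EIPartition([0], [1])
        rep = ei_balance_certificate(state.w, part, model, tolerance=0.0)
        inner = static_symmetric_part_certificate(state.w, model)
        assert rep.passed == inner.passed
        assert rep.margin == pytest.approx(inner.margin, abs=1e-12)

    def test_invalid_partition_rejected(self):
        model, _, state = fixtures.ei_population_network(4, 4, seed=0)
        with pytest.raises(ValueError):
            ei_balance_certificate(
                state.w, EIPartition([0, 1], [2, 3]), model
            )


class TestESNCheck:
    def test_margins(self):
        rep = esn_discrete_contraction_check(0.5 * np.eye(3))
        assert rep.passed and rep.margin == pytest.approx(0.5, abs=1e-12)
        assert not esn_discrete_contraction_check(2.0 * np.eye(3)).passed

    def test_scaled_orthogonal(self):
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        rep = esn_discrete_contraction_check(0.9 * q)
        assert rep.margin == pytest.approx(0.1, abs=1e-10)


class TestCounterexampleDemo:
    def test_eigenvalues_constant_but_trajectory_grows(self):
        demo = eigenvalue_test_insufficiency_demo()
        np.testing.assert_allclose(demo["eigenvalues"], -1.0, atol=1e-12)
        x = demo["trajectory"][:, 0]
        assert np.all(np.diff(x) >= 0)  # monotone growth despite stable eigenvalues
        assert demo["max_abs_error"] <= 1e-4

    def test_closed_form_values(self):
        demo = eigenvalue_test_insufficiency_demo()
        times = demo["times"]
        idx = np.argmin(np.abs(times - 1.0))
        assert demo["trajectory"][idx, 0] == pytest.approx(np.sinh(1.0), abs=1e-6)
        assert demo["mu2_zero_crossing"] == pytest.approx(np.log(2.0) / 2.0, abs=1e-9)
        a0 = fixtures.counterexample_system()[0](0.0)
        assert mu2(a0) == pytest.approx(-0.5, abs=1e-12)


def test_report_json_round_trip():
    model, state = fixtures.two_neuron_ei(0.5)
    rep = static_symmetric_part_certificate(state.w, model)
    payload = json.loads(rep.to_json())
    assert payload["certificate"] == "static_symmetric_part"
    assert payload["passed"] is True
    assert payload["margins"] == [pytest.approx(0.5)]
    assert list(payload) == [
        "certificate", "passed", "margins", "details", "assumptions_checked",
    ]
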