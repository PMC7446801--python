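"""Stability certificates for plastic and static rate networks.

Each certificate checks the hypotheses of a sufficient condition for
contraction and reports per-neuron (or per-condition) margins:

* ``hebbian_contraction_certificate`` — inhibitory-Hebbian / excitatory-
  anti-Hebbian plasticity with an admissible learning-rate matrix K makes the
  joint neural+synaptic system contracting; verified numerically via the
  log-norm of the metric-transformed Jacobian along a test trajectory.
* ``sparsity_certificate`` — per-neuron afferent-count inequality
  p_i (g_max w_max + alpha_i r_max) < beta_i.
* ``static_symmetric_part_certificate`` — for frozen weights, contraction is
  governed by lambda_max of the symmetric part of W.
* ``ei_balance_certificate`` — matched-amplitude E->I / I->E connections
  cancel in the symmetric part regardless of amplitude.
* ``esn_discrete_contraction_check`` — discrete-time echo-state condition
  g_max * sigma_max(W) < 1.

``eigenvalue_test_insufficiency_demo`` reproduces the classic time-varying
counterexample showing that frozen-time eigenvalues do not determine the
stability of dx/dt = A(t) x, motivating the symmetric-part (log-norm) tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse.linalg

from .dynamics import NetworkState, NeuralModelSpec, PlasticitySpec, combined_jacobian
from .lognorm import Metric, SYMMETRY_RTOL, mu2, sym_part

__all__ = [
    "CertificateReport",
    "SparsityProfile",
    "EIPartition",
    "check_plasticity_hypotheses",
    "hebbian_contraction_certificate",
    "hebbian_metric",
    "mu2_combined_in_k_metric",
    "sparsity_certificate",
    "static_symmetric_part_certificate",
    "ei_balance_certificate",
    "eigenvalue_test_insufficiency_demo",
    "esn_discrete_contraction_check",
]


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------


@dataclass
class CertificateReport:
    """Outcome of a stability certificate.

    ``passed`` is true only if every named hypothesis check passed and every
    margin is strictly positive.  Margins are certificate-specific (rate
    units for the per-neuron inequalities).
    """

    certificate_name: str
    passed: bool
    margins: np.ndarray
    details: dict = field(default_factory=dict)
    assumptions_checked: list = field(default_factory=list)  # (name, bool) pairs

    @property
    def margin(self) -> float:
        return float(np.min(self.margins)) if np.size(self.margins) else float("nan")

    def failed_assumptions(self) -> list:
        return [name for name, ok in self.assumptions_checked if not ok]

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "certificate": self.certificate_name,
            "passed": bool(self.passed),
            "margins": _clean(np.atleast_1d(self.margins)),
            "details": _clean(self.details),
            "assumptions_checked": [
                {"name": n, "passed": bool(ok)} for n, ok in self.assumptions_checked
            ],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), sort_keys=False, **kwargs)


def _finalize(name, checks, margins, details) -> CertificateReport:
    margins = np.atleast_1d(np.asarray(margins, dtype=float))
    passed = all(ok for _, ok in checks) and bool(np.all(margins > 0))
    return CertificateReport(
        certificate_name=name,
        passed=passed,
        margins=margins,
        details=details,
        assumptions_checked=checks,
    )


# ---------------------------------------------------------------------------
# sparsity / E-I domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SparsityProfile:
    """Afferent-synapse counts and bounds entering the sparsity inequality.

    p_per_neuron — number of afferent synapses into each neuron;
    alpha_per_neuron — fraction of those that are plastic, in [0, 1];
    w_max — maximum possible |w_ij| over all synapses.
    """

    p_per_neuron: np.ndarray
    alpha_per_neuron: np.ndarray
    w_max: float

    def __post_init__(self):
        p = np.atleast_1d(np.asarray(self.p_per_neuron))
        a = np.atleast_1d(np.asarray(self.alpha_per_neuron, dtype=float))
        p, a = np.broadcast_arrays(p, a)
        if np.any(p < 0):
            raise ValueError("afferent counts p_i must be nonnegative")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("plastic fractions alpha_i must lie in [0, 1]")
        if self.w_max < 0:
            raise ValueError("w_max must be nonnegative")
        object.__setattr__(self, "p_per_neuron", p.astype(float).copy())
        object.__setattr__(self, "alpha_per_neuron", a.copy())


@dataclass(frozen=True)
class EIPartition:
    """Disjoint excitatory / inhibitory index sets covering all neurons."""

    excitatory: np.ndarray
    inhibitory: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.excitatory, dtype=int)
        i = np.asarray(self.inhibitory, dtype=int)
        object.__setattr__(self, "excitatory", e)
        object.__setattr__(self, "inhibitory", i)

    def validate(self, n: int) -> None:
        all_idx = np.concatenate([self.excitatory, self.inhibitory])
        if len(set(all_idx.tolist())) != len(all_idx) or sorted(all_idx) != list(
            range(n)
        ):
            raise ValueError(
                "E/I partition must cover all neuron indices exactly once"
            )


# ---------------------------------------------------------------------------
# plasticity hypotheses
# ---------------------------------------------------------------------------


def check_plasticity_hypotheses(plasticity: PlasticitySpec) -> CertificateReport:
    """Check the admissibility of K: symmetric, entrywise positive, PSD.

    Failures are reported in ``assumptions_checked``, never raised.
    """
    k = plasticity.k_matrix
    scale = max(float(np.linalg.norm(k)), 1.0)
    symmetric = bool(np.allclose(k, k.T, rtol=0, atol=SYMMETRY_RTOL * scale))
    positive_entries = bool(np.all(k > 0))
    evals = scipy.linalg.eigvalsh(0.5 * (k + k.T))
    psd = bool(evals[0] >= -1e-10 * scale)
    checks = [
        ("k_symmetric", symmetric),
        ("k_entrywise_positive", positive_entries),
        ("k_positive_semidefinite", psd),
    ]
    # margin: smallest eigenvalue of sym(K) plus the PSD floor (numerical slack)
    margins = np.array([evals[0] + 1e-10 * scale])
    return _finalize(
        "plasticity_hypotheses",
        checks,
        margins,
        {"k_eigenvalues": evals, "k_min_entry": float(np.min(k))},
    )


# ---------------------------------------------------------------------------
# hebbian plasticity certificate
# ---------------------------------------------------------------------------


def hebbian_metric(plasticity: PlasticitySpec) -> Metric:
    """Diagonal metric rescaling each synaptic coordinate W_ij by 1/sqrt(k_ij).

    Identity on the neural block.  This is the scaling that makes the
    neural->synaptic and synaptic->neural Jacobian cross-blocks (nearly)
    equal-and-opposite pairs; its adequacy is verified numerically by the
    certificate, not assumed.
    """
    k = plasticity.k_matrix
    if np.any(k <= 0):
        raise ValueError("metric requires entrywise-positive K")
    n = k.shape[0]
    scales = np.concatenate([np.ones(n), (1.0 / np.sqrt(k)).ravel()])
    return Metric.diagonal(scales)


def mu2_combined_in_k_metric(
    state: NetworkState,
    model: NeuralModelSpec,
    plasticity: PlasticitySpec,
    t: float = 0.0,
    dense_threshold: int = 900,
) -> float:
    """mu2 of the combined Jacobian in the K-rescaled metric.

    For small systems the transformed Jacobian is built densely; for large
    ones lambda_max of its symmetric part is computed matrix-free from the
    block structure (identity activation required on the fast path).
    """
    n = state.n
    dim = n + n * n
    if dim <= dense_threshold:
        jac = combined_jacobian(state, model, plasticity, t)
        theta = hebbian_metric(plasticity)
        transformed = np.linalg.solve(theta.theta.T, (theta.theta @ jac).T).T
        return mu2(transformed)

    if model.activation != "identity":
        raise ValueError("matrix-free path requires the identity activation")
    x, w = state.x, state.w
    k = plasticity.k_matrix
    sqrt_k = np.sqrt(k)
    gamma = plasticity.gamma_at(t)
    a_sym = sym_part(np.diag(model.h_prime(x)) + w * model.r_prime(x)[None, :])

    # symmetric part of the theta-transformed Jacobian, acting on (u, V):
    #   top    = sym(A) u - 0.5 (sqrt_k o V)^T x
    #   bottom = -gamma V - 0.5 sqrt_k o (x u^T)
    def matvec(z):
        u = z[:n]
        v = z[n:].reshape(n, n)
        sv = sqrt_k * v
        top = a_sym @ u - 0.5 * (sv.T @ x)
        bottom = -gamma * v - 0.5 * sqrt_k * np.outer(x, u)
        return np.concatenate([top, bottom.ravel()])

    op = scipy.sparse.linalg.LinearOperator((dim, dim), matvec=matvec, dtype=float)
    val = scipy.sparse.linalg.eigsh(
        op, k=1, which="LA", return_eigenvectors=False, tol=1e-9, maxiter=5000
    )
    return float(val[0])


def hebbian_contraction_certificate(
    model: NeuralModelSpec,
    plasticity: PlasticitySpec,
    horizon: float = 10.0,
    dt: float = 1e-2,
    n_samples: int = 50,
    tail_fraction: float = 0.5,
    seed: int = 0,
    initial: Optional[NetworkState] = None,
) -> CertificateReport:
    """Certify contraction of the combined system under correlational plasticity.

    Hypotheses: identity activation (the linear-rate model), admissible K
    (symmetric, entrywise positive, PSD) and gamma > 0 on the horizon.  The
    certificate then integrates an input-free test trajectory from U(-1, 1)
    initial conditions and samples mu2 of the Jacobian in the K-rescaled
    metric; it passes iff mu2 < 0 at every sampled time in the trajectory
    tail (last ``tail_fraction`` of the horizon).  The initial transient is
    excluded: with generic U(-1, 1) weights, lambda_max(sym W(0)) typically
    exceeds the leak rate and this fixed diagonal metric is transiently
    positive before plasticity and forgetting symmetrise and shrink W.

    Margins are -mu2 at the sampled tail times; details include the full
    sampled mu2 series.
    """
    from .simulate import SimulationProtocol, draw_initial_state, integrate

    hyp = check_plasticity_hypotheses(plasticity)
    checks = list(hyp.assumptions_checked)
    checks.append(("identity_activation", model.activation == "identity"))

    grid = np.linspace(0.0, horizon, max(n_samples, 2))
    gamma_vals = np.array([plasticity.gamma_at(t) for t in grid])
    checks.append(("gamma_positive", bool(np.all(gamma_vals > 0))))

    details: dict = {"metric": "K-rescaled (implementation choice)"}
    if not all(ok for _, ok in checks):
        return _finalize(
            "hebbian_contraction", checks, np.array([-np.inf]), details
        )

    rng = np.random.default_rng(seed)
    if initial is None:
        initial = draw_initial_state(model.n, rng, plastic=True)
    protocol = SimulationProtocol(t_end=horizon, dt=dt, seed=seed)
    result = integrate(model, plasticity, protocol, initial)

    sample_idx = np.unique(
        np.linspace(0, len(result.times) - 1, n_samples).astype(int)
    )
    mu2_series = np.array(
        [
            mu2_combined_in_k_metric(
                result.state_at(i), model, plasticity, t=result.times[i]
            )
            for i in sample_idx
        ]
    )
    sample_times = result.times[sample_idx]
    tail = sample_times >= (1.0 - tail_fraction) * horizon
    margins = -mu2_series[tail]
    details.update(
        {
            "sample_times": sample_times,
            "mu2_series": mu2_series,
            "tail_start_time": float((1.0 - tail_fraction) * horizon),
            "max_tail_mu2": float(np.max(mu2_series[tail])),
            "verification_horizon": horizon,
        }
    )
    return _finalize("hebbian_contraction", checks, margins, details)


# ---------------------------------------------------------------------------
# sparsity certificate
# ---------------------------------------------------------------------------


def sparsity_certificate(
    model: NeuralModelSpec, sparsity: SparsityProfile
) -> CertificateReport:
    """Per-neuron afferent-count inequality p_i (g_max w_max + alpha_i r_max) < beta_i.

    Margins are beta_i - p_i (g_max w_max + alpha_i r_max); the network is
    certified contracting iff every margin is strictly positive.  The plastic
    term alpha_i r_max requires a bounded activation; an unbounded r_max with
    any alpha_i > 0 raises a precondition error.
    """
    p = np.broadcast_to(sparsity.p_per_neuron, (model.n,))
    alpha = np.broadcast_to(sparsity.alpha_per_neuron, (model.n,))
    if np.any(alpha > 0) and not np.isfinite(model.r_max):
        raise ValueError(
            "sparsity certificate with plastic synapses (alpha_i > 0) requires "
            "a bounded activation (finite r_max); the derivation assumes "
            "bounded r"
        )
    r_max = model.r_max if np.isfinite(model.r_max) else 0.0
    load = p * (model.g_max * sparsity.w_max + alpha * r_max)
    margins = model.beta_per_neuron - load
    checks = [("bounded_r_for_plastic_synapses", True)]
    return _finalize(
        "sparsity",
        checks,
        margins,
        {
            "g_max": model.g_max,
            "w_max": sparsity.w_max,
            "r_max": model.r_max,
            "per_neuron_load": load,
        },
    )


# ---------------------------------------------------------------------------
# static-weight certificates
# ---------------------------------------------------------------------------


def static_symmetric_part_certificate(
    w, model: NeuralModelSpec
) -> CertificateReport:
    """Contraction test for frozen weights via the symmetric part of W.

    Passes iff g_max * lambda_max(sym(W)) < min_i beta_i; the margin is the
    difference.  Frozen-time eigenvalues of W itself are *not* a valid test
    (see :func:`eigenvalue_test_insufficiency_demo`).
    """
    w = np.asarray(w, dtype=float)
    lam = float(scipy.linalg.eigvalsh(sym_part(w))[-1])
    beta_min = float(np.min(model.beta_per_neuron))
    margin = beta_min - model.g_max * lam
    return _finalize(
        "static_symmetric_part",
        [],
        np.array([margin]),
        {"lambda_max_sym_w": lam, "beta_min": beta_min, "g_max": model.g_max},
    )


def ei_balance_certificate(
    w,
    partition: EIPartition,
    model: NeuralModelSpec,
    tolerance: float = 0.05,
) -> CertificateReport:
    """Excitatory-inhibitory balance test for static weights.

    With W_EI the (E rows, I cols) block and W_IE the (I rows, E cols) block,
    exact balance W_EI = -W_IE^T makes the cross blocks cancel in sym(W), so
    stability is set by the within-population blocks alone — regardless of
    cross-connection amplitude.  ``tolerance`` admits "statistical" balance:
    the relative residual ||W_EI + W_IE^T|| / (||W_EI|| + ||W_IE||) must not
    exceed it (the residual itself still enters the symmetric-part test,
    which is applied to the full W).

    Sign conventions checked: E -> I connections nonnegative, I -> E
    connections nonpositive.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    partition.validate(n)
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    e, i = partition.excitatory, partition.inhibitory
    w_ei = w[np.ix_(e, i)]  # I -> E connections
    w_ie = w[np.ix_(i, e)]  # E -> I connections

    checks = [
        ("e_to_i_nonnegative", bool(np.all(w_ie >= 0))),
        ("i_to_e_nonpositive", bool(np.all(w_ei <= 0))),
    ]
    cross_scale = float(np.linalg.norm(w_ei, 2) + np.linalg.norm(w_ie, 2))
    residual = float(np.linalg.norm(w_ei + w_ie.T, 2))
    rel_residual = residual / cross_scale if cross_scale > 0 else 0.0
    checks.append(("cross_blocks_balanced", rel_residual <= tolerance))

    inner = static_symmetric_part_certificate(w, model)
    checks.extend(inner.assumptions_checked)
    details = {
        "cross_residual_relative": rel_residual,
        "cross_residual_norm": residual,
        "tolerance": tolerance,
        **inner.details,
    }
    return _finalize("ei_balance", checks, inner.margins, details)


def esn_discrete_contraction_check(w, g_max: float = 1.0) -> CertificateReport:
    """Discrete-time contraction check for echo-state-style updates.

    For x+ = r(W x + u) with activation gain at most g_max, the map is a
    contraction in the Euclidean norm iff g_max * sigma_max(W) < 1; the
    margin is 1 - g_max * sigma_max(W).
    """
    w = np.asarray(w, dtype=float)
    if g_max <= 0:
        raise ValueError("g_max must be positive")
    sigma = float(np.linalg.norm(w, 2))
    margin = 1.0 - g_max * sigma
    return _finalize(
        "esn_discrete_contraction",
        [],
        np.array([margin]),
        {"sigma_max": sigma, "g_max": g_max},
    )


# ---------------------------------------------------------------------------
# time-varying counterexample
# ---------------------------------------------------------------------------


def eigenvalue_test_insufficiency_demo(
    t_end: float = 2.0,
    dt: float = 1e-4,
    n_samples: int = 21,
) -> dict:
    """Why frozen-time eigenvalues cannot certify time-varying stability.

    The system dx/dt = -x + e^{2t} y, dy/dt = -y has A(t) upper triangular
    with eigenvalues (-1, -1) at every t, yet from (x, y)(0) = (0, 1) the
    solution is y(t) = e^{-t}, x(t) = sinh(t): the x-component grows without
    bound.  mu2(A(t)) = -1 + e^{2t}/2 correctly flags the instability,
    turning positive at t = ln(2)/2.

    Returns sampled eigenvalues, the closed-form and numerically integrated
    trajectories, the sampled mu2 series and its zero-crossing time.
    """
    from .fixtures import counterexample_system
    from .simulate import integrate_ode

    a_of_t, x_closed, y_closed = counterexample_system()
    sample_times = np.linspace(0.0, t_end, n_samples)
    eigenvalues = np.array(
        [sorted(np.linalg.eigvals(a_of_t(t)).real) for t in sample_times]
    )
    mu2_series = np.array([mu2(a_of_t(t)) for t in sample_times])

    times, traj = integrate_ode(
        lambda t, z: a_of_t(t) @ z, np.array([0.0, 1.0]), t_end, dt
    )
    closed = np.column_stack([x_closed(times), y_closed(times)])
    crossing = float(
        scipy.optimize.brentq(lambda t: mu2(a_of_t(t)), 0.0, max(t_end, 1.0))
    )
    return {
        "sample_times": sample_times,
        "eigenvalues": eigenvalues,
        "mu2_series": mu2_series,
        "mu2_zero_crossing": crossing,
        "times": times,
        "trajectory": traj,
        "closed_form": closed,
        "max_abs_error": float(np.max(np.abs(traj - closed))),
    }
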