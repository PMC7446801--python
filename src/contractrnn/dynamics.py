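"""Right-hand sides and Jacobians for rate networks with correlational plasticity.

The neural subsystem is

    dx_i/dt = h(x_i) + sum_j W_ij r(x_j) + u_i(t)

where x_i is the deviation of neuron i's firing rate from baseline (it may be
negative), h is a leak with h'(x) < 0 (default h(x) = -x), r the activation
(identity or tanh), and u a bounded external input.  Self-feedback from the
weight-matrix diagonal is folded into h, so fixtures zero diag(W).

The synaptic subsystem is the correlational rule

    dW_ij/dt = -k_ij x_i x_j - gamma(t) W_ij

which is Hebbian for inhibitory synapses and anti-Hebbian for excitatory ones:
correlated activity makes inhibitory weights more efficient (|w| grows) and
excitatory weights less efficient.

The combined state lives in R^(n + n^2), packed as [x; rows of W row-major].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "NeuralModelSpec",
    "PlasticitySpec",
    "NetworkState",
    "InputSpec",
    "neural_rhs",
    "plasticity_rhs",
    "classify_plasticity_effect",
    "combined_rhs",
    "combined_jacobian",
]


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

_LEAKS = {
    # name -> (h, h')
    "linear": (lambda x, beta: -beta * x, lambda x, beta: -beta * np.ones_like(x)),
}

_ACTIVATIONS = {
    # name -> (r, r', g_max, r_max)
    "identity": (lambda x: x, lambda x: np.ones_like(x), 1.0, np.inf),
    "tanh": (lambda x: np.tanh(x), lambda x: 1.0 / np.cosh(x) ** 2, 1.0, 1.0),
}


@dataclass(frozen=True)
class NeuralModelSpec:
    """Leak and activation of the neural subsystem, plus derived rate bounds.

    Parameters
    ----------
    n:
        Number of neurons.
    leak:
        Named leak function; ``"linear"`` is h(x) = -beta x.
    activation:
        ``"identity"`` (the linear-rate model) or ``"tanh"`` (saturating).
    beta:
        Isolated-neuron contraction rate(s) beta_i = -max_x h'(x), scalar or
        per-neuron.  All must be strictly positive.
    """

    n: int
    leak: str = "linear"
    activation: str = "identity"
    beta: float | np.ndarray = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.leak not in _LEAKS:
            raise ValueError(f"unknown leak {self.leak!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        beta = np.broadcast_to(np.asarray(self.beta, dtype=float), (self.n,)).copy()
        if np.any(beta <= 0):
            raise ValueError("beta must be strictly positive (h is a leak)")
        object.__setattr__(self, "beta", beta)

    # -- leak -------------------------------------------------------------
    def h(self, x: np.ndarray) -> np.ndarray:
        return _LEAKS[self.leak][0](x, self.beta)

    def h_prime(self, x: np.ndarray) -> np.ndarray:
        return _LEAKS[self.leak][1](x, self.beta)

    # -- activation -------------------------------------------------------
    def r(self, x: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.activation][0](x)

    def r_prime(self, x: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.activation][1](x)

    @property
    def g_max(self) -> float:
        """Maximum neuronal gain max |r'|."""
        return _ACTIVATIONS[self.activation][2]

    @property
    def r_max(self) -> float:
        """Maximum |r|; infinite for the identity activation."""
        return _ACTIVATIONS[self.activation][3]

    @property
    def beta_per_neuron(self) -> np.ndarray:
        return self.beta


@dataclass(frozen=True)
class PlasticitySpec:
    """Learning-rate matrix K and forgetting rate gamma(t).

    ``k_matrix`` holds per-synapse learning rates k_ij; ``gamma`` is either a
    nonnegative constant or a callable of time.  The contraction theorem for
    this rule additionally requires K symmetric, entrywise positive and
    positive semi-definite — those hypotheses are *checked*, not assumed, by
    ``certificates.check_plasticity_hypotheses``.
    """

    k_matrix: np.ndarray
    gamma: float | Callable[[float], float] = 1.0

    def __post_init__(self):
        k = np.asarray(self.k_matrix, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("k_matrix must be square")
        if not np.all(np.isfinite(k)):
            raise ValueError("k_matrix contains non-finite entries")
        object.__setattr__(self, "k_matrix", k)

    @property
    def n(self) -> int:
        return self.k_matrix.shape[0]

    def gamma_at(self, t: float) -> float:
        g = self.gamma(t) if callable(self.gamma) else self.gamma
        return float(g)

    @classmethod
    def uniform(cls, n: int, k: float = 1.0, gamma: float = 1.0) -> "PlasticitySpec":
        """Equal learning rates k_ij = k (all-ones pattern, rank-1 PSD)."""
        return cls(k * np.ones((n, n)), gamma)

    @classmethod
    def static(cls, n: int) -> "PlasticitySpec":
        """Frozen weights: K = 0, gamma = 0 (the weight block does not move)."""
        return cls(np.zeros((n, n)), 0.0)


@dataclass
class NetworkState:
    """Joint neural + synaptic state (x, W) at one time point.

    The flattened vector has length n + n^2, laid out as [x; W row-major].
    """

    x: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.w = np.asarray(self.w, dtype=float)
        n = self.x.shape[0]
        if self.w.shape != (n, n):
            raise ValueError(f"w must be {n}x{n}, got {self.w.shape}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.w))):
            raise ValueError("state contains non-finite entries")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.x, self.w.ravel()])

    @classmethod
    def unflatten(cls, z: np.ndarray, n: int) -> "NetworkState":
        z = np.asarray(z, dtype=float).ravel()
        if z.shape[0] != n + n * n:
            raise ValueError(f"flattened state must have length {n + n * n}")
        return cls(z[:n], z[n:].reshape(n, n))


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputSpec:
    """Per-neuron external input u(t).

    ``sinusoid_bank`` realises u_i(t) = a_i sin(2 pi f_i t + phi_i); ``none``
    is the autonomous case.  ``custom_samples`` wraps an arbitrary callable.
    """

    kind: str = "none"  # none | sinusoid_bank | custom_samples
    n: int = 0
    frequencies: Optional[np.ndarray] = None
    phases: Optional[np.ndarray] = None
    amplitudes: Optional[np.ndarray] = None
    func: Optional[Callable[[float], np.ndarray]] = field(default=None, repr=False)

    def __call__(self, t: float) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(self.n)
        if self.kind == "sinusoid_bank":
            return self.amplitudes * np.sin(
                2.0 * np.pi * self.frequencies * t + self.phases
            )
        if self.kind == "custom_samples":
            return np.asarray(self.func(t), dtype=float)
        raise ValueError(f"unknown input kind {self.kind!r}")

    @classmethod
    def none(cls, n: int) -> "InputSpec":
        return cls(kind="none", n=n)

    @classmethod
    def sinusoids(cls, frequencies, phases, amplitudes) -> "InputSpec":
        f = np.asarray(frequencies, dtype=float)
        p = np.asarray(phases, dtype=float)
        a = np.asarray(amplitudes, dtype=float)
        if not f.shape == p.shape == a.shape:
            raise ValueError("frequencies, phases, amplitudes must share a shape")
        return cls(
            kind="sinusoid_bank", n=f.shape[0], frequencies=f, phases=p, amplitudes=a
        )


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def neural_rhs(
    state: NetworkState, model: NeuralModelSpec, input_value: np.ndarray
) -> np.ndarray:
    """dx/dt = h(x) + W r(x) + u, elementwise over neurons."""
    u = np.asarray(input_value, dtype=float).ravel()
    if u.shape[0] != state.n or model.n != state.n:
        raise ValueError("dimension mismatch between state, model and input")
    return model.h(state.x) + state.w @ model.r(state.x) + u


def plasticity_rhs(
    state: NetworkState, plasticity: PlasticitySpec, t: float = 0.0
) -> np.ndarray:
    """dW/dt = -K o (x x^T) - gamma(t) W (o = entrywise product)."""
    if plasticity.n != state.n:
        raise ValueError("K dimensions do not match the state")
    outer = np.outer(state.x, state.x)
    return -plasticity.k_matrix * outer - plasticity.gamma_at(t) * state.w


def classify_plasticity_effect(w_sign: str, correlation_sign: str) -> str:
    """Predicted change in synaptic efficiency |w| under the correlational rule.

    The drive term -k x_i x_j moves excitatory weights (w > 0) toward zero for
    correlated activity (anti-Hebbian) and strengthens inhibitory weights
    (w < 0) for correlated activity (Hebbian); the decay term is ignored.
    """
    if w_sign not in ("excitatory", "inhibitory"):
        raise ValueError(f"w_sign must be excitatory|inhibitory, got {w_sign!r}")
    if correlation_sign not in ("correlated", "anticorrelated"):
        raise ValueError(
            f"correlation_sign must be correlated|anticorrelated, got {correlation_sign!r}"
        )
    correlated = correlation_sign == "correlated"
    excitatory = w_sign == "excitatory"
    # drive sign of d|w|/dt: -sign(w) * sign(x_i x_j)
    return "less_efficient" if excitatory == correlated else "more_efficient"


def combined_rhs(
    state: NetworkState,
    model: NeuralModelSpec,
    plasticity: PlasticitySpec,
    input_value: np.ndarray,
    t: float = 0.0,
) -> np.ndarray:
    """Flattened RHS of the joint neural + synaptic system, length n + n^2."""
    dx = neural_rhs(state, model, input_value)
    dw = plasticity_rhs(state, plasticity, t)
    return np.concatenate([dx, dw.ravel()])


def combined_jacobian(
    state: NetworkState,
    model: NeuralModelSpec,
    plasticity: PlasticitySpec,
    t: float = 0.0,
) -> np.ndarray:
    """Exact analytic Jacobian of :func:`combined_rhs`, size (n+n^2)^2.

    Blocks (row-major weight flattening, index (i,j) -> i*n + j):

    * d(dx)/dx   = diag(h'(x)) + W diag(r'(x))
    * d(dx_i)/dW_kl = delta_ik r(x_l)
    * d(dW_ij)/dx_m = -k_ij (delta_im x_j + delta_jm x_i)
    * d(dW)/dW  = -gamma(t) I
    """
    n = state.n
    x, w = state.x, state.w
    k = plasticity.k_matrix
    gamma = plasticity.gamma_at(t)
    dim = n + n * n
    jac = np.zeros((dim, dim))

    # neural block
    jac[:n, :n] = np.diag(model.h_prime(x)) + w * model.r_prime(x)[None, :]

    # d(dx_i)/dW_il = r(x_l)
    rx = model.r(x)
    for i in range(n):
        jac[i, n + i * n : n + (i + 1) * n] = rx

    # d(dW_ij)/dx: row n + i*n + j gets -k_ij x_j at column i and -k_ij x_i at j
    rows = n + np.arange(n * n)
    ii, jj = np.divmod(np.arange(n * n), n)
    np.add.at(jac, (rows, ii), -k[ii, jj] * x[jj])
    np.add.at(jac, (rows, jj), -k[ii, jj] * x[ii])

    # weight block
    jac[n:, n:] -= gamma * np.eye(n * n)
    return jac
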