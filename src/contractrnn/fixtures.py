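"""Seeded network generators used throughout tests and figure reproduction.

Every generator is deterministic given its seed: the same arguments always
produce bit-identical arrays.  The defaults encode the study conditions used
for the distance-convergence and weight-symmetrisation figures: unit
parameters and time constants, initial conditions uniform on [-1, 1], equal
learning rates K = k * ones, constant forgetting gamma, and zero weight-
matrix diagonal (self-feedback lives in the leak term).
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .certificates import EIPartition, SparsityProfile
from .dynamics import NetworkState, NeuralModelSpec, PlasticitySpec

__all__ = [
    "random_plastic_network",
    "sparse_static_network",
    "two_neuron_ei",
    "ei_population_network",
    "counterexample_system",
    "FIXTURE_REGISTRY",
]


def random_plastic_network(
    n: int = 100,
    k: float = 1.0,
    gamma: float = 1.0,
    seed: int = 0,
) -> tuple[NeuralModelSpec, PlasticitySpec, NetworkState]:
    """Random linear-rate network with uniform correlational plasticity.

    h(x) = -x, identity activation, K = k * ones (rank-1 PSD with positive
    entries), constant gamma; x(0) and W(0) drawn uniformly on [-1, 1] with
    diag(W(0)) = 0.  ``n=100, k=gamma=1`` is the figure-reproduction fixture.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-1.0, 1.0, size=n)
    w0 = rng.uniform(-1.0, 1.0, size=(n, n))
    np.fill_diagonal(w0, 0.0)
    model = NeuralModelSpec(n=n, leak="linear", activation="identity", beta=1.0)
    plasticity = PlasticitySpec.uniform(n, k=k, gamma=gamma)
    return model, plasticity, NetworkState(x0, w0)


def sparse_static_network(
    n: int,
    p: int,
    w_max: float,
    activation: str = "identity",
    seed: int = 0,
) -> tuple[NeuralModelSpec, SparsityProfile, NetworkState]:
    """Static network where every neuron receives exactly p afferent synapses.

    Afferents are placed at uniformly random presynaptic positions (no
    self-connections), with weights ~ U(-w_max, w_max).  All synapses are
    static (alpha = 0), so the sparsity inequality reduces to
    p * g_max * w_max < beta.
    """
    if not 0 <= p <= n - 1:
        raise ValueError(f"p must lie in [0, n-1], got p={p}, n={n}")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        candidates = np.delete(np.arange(n), i)
        afferents = rng.choice(candidates, size=p, replace=False)
        w[i, afferents] = rng.uniform(-w_max, w_max, size=p)
    model = NeuralModelSpec(n=n, activation=activation, beta=1.0)
    profile = SparsityProfile(
        p_per_neuron=np.full(n, p), alpha_per_neuron=np.zeros(n), w_max=w_max
    )
    x0 = rng.uniform(-1.0, 1.0, size=n)
    return model, profile, NetworkState(x0, w)


def two_neuron_ei(w: float) -> tuple[NeuralModelSpec, NetworkState]:
    """The recurrent pair of one excitatory and one inhibitory neuron.

    W = [[w, -w], [w, -w]]: the off-diagonal elements cancel in the symmetric
    part, leaving diag(w, -w) — so contraction holds whenever w is below the
    isolated-neuron leak rate, regardless of how strong the E-I coupling is.
    """
    model = NeuralModelSpec(n=2, activation="identity", beta=1.0)
    weights = np.array([[w, -w], [w, -w]], dtype=float)
    return model, NetworkState(np.zeros(2), weights)


def ei_population_network(
    n_e: int,
    n_i: int,
    cross_scale: float = 1.0,
    within_scale: float = 0.05,
    exact: bool = True,
    seed: int = 0,
) -> tuple[NeuralModelSpec, EIPartition, NetworkState]:
    """Excitatory and inhibitory populations with balanced cross-connections.

    Neurons 0..n_e-1 are excitatory, the rest inhibitory.  Cross blocks obey
    Dale's sign convention (E -> I nonnegative, I -> E nonpositive), scaled
    by ``cross_scale``; with ``exact=True`` they satisfy W_EI = -W_IE^T
    entry-for-entry, otherwise they are drawn independently with matched mean
    amplitude (balance holds statistically, improving with population size).
    Within-population weights are scaled by ``within_scale`` with E columns
    nonnegative and I columns nonpositive.
    """
    if n_e < 1 or n_i < 1:
        raise ValueError("population sizes must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_e + n_i
    w = np.zeros((n, n))
    e = np.arange(n_e)
    i = np.arange(n_e, n)

    # within-population blocks, Dale sign by presynaptic (column) type
    w_ee = rng.uniform(0.0, within_scale, size=(n_e, n_e))
    np.fill_diagonal(w_ee, 0.0)
    w_ii = -rng.uniform(0.0, within_scale, size=(n_i, n_i))
    np.fill_diagonal(w_ii, 0.0)
    w[np.ix_(e, e)] = w_ee
    w[np.ix_(i, i)] = w_ii

    # cross blocks
    w_ie = cross_scale * rng.uniform(0.0, 1.0, size=(n_i, n_e))  # E -> I, >= 0
    if exact:
        w_ei = -w_ie.T  # I -> E, exactly balanced
    else:
        w_ei = -cross_scale * rng.uniform(0.0, 1.0, size=(n_e, n_i))
    w[np.ix_(i, e)] = w_ie
    w[np.ix_(e, i)] = w_ei

    model = NeuralModelSpec(n=n, activation="identity", beta=1.0)
    partition = EIPartition(excitatory=e, inhibitory=i)
    x0 = rng.uniform(-1.0, 1.0, size=n)
    return model, partition, NetworkState(x0, w)


def counterexample_system() -> tuple[
    Callable[[float], np.ndarray],
    Callable[[np.ndarray], np.ndarray],
    Callable[[np.ndarray], np.ndarray],
]:
    """The time-varying linear system A(t) = [[-1, e^{2t}], [0, -1]].

    Returns (A, x_closed, y_closed) where the closed forms solve the system
    from (x, y)(0) = (0, 1): y(t) = e^{-t} and x(t) = sinh(t).  A(t) is
    triangular with eigenvalues (-1, -1) for all t, yet x grows unboundedly —
    frozen-time eigenvalues do not determine time-varying stability.
    """

    def a_of_t(t: float) -> np.ndarray:
        return np.array([[-1.0, np.exp(2.0 * t)], [0.0, -1.0]])

    def x_closed(t):
        return np.sinh(np.asarray(t, dtype=float))

    def y_closed(t):
        return np.exp(-np.asarray(t, dtype=float))

    return a_of_t, x_closed, y_closed


#: name -> (factory, default kwargs); the CLI's ``fixtures`` verbs use this
FIXTURE_REGISTRY: dict = {
    "random_plastic": (
        random_plastic_network,
        {"n": 100, "k": 1.0, "gamma": 1.0, "seed": 0},
    ),
    "sparse_static": (
        sparse_static_network,
        {"n": 30, "p": 3, "w_max": 0.1, "activation": "identity", "seed": 0},
    ),
    "two_neuron_ei": (two_neuron_ei, {"w": 0.5}),
    "ei_population": (
        ei_population_network,
        {
            "n_e": 10,
            "n_i": 10,
            "cross_scale": 1.0,
            "within_scale": 0.05,
            "exact": True,
            "seed": 0,
        },
    ),
}
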