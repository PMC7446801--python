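"""Numerical integration of the neural + synaptic system.

Deterministic runs use a fixed-step classical RK4 scheme; stochastic runs use
Euler–Maruyama with independent Wiener increments driving the *neural*
coordinates only (noise perturbs firing rates, not weights).  The input,
pulse-perturbation and noise protocols follow the simulation recipe used for
the distance-convergence figures: dt = 1e-2, initial conditions uniform on
[-1, 1], a pulse adding a vector of all 10s for 100 steps mid-run, and
sinusoid input banks with frequencies ~ U(dt, 100 dt), phases ~ U(0, 2 pi),
amplitudes ~ U(0, 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .dynamics import (
    InputSpec,
    NetworkState,
    NeuralModelSpec,
    PlasticitySpec,
    combined_rhs,
    neural_rhs,
)

__all__ = [
    "SimulationProtocol",
    "SimulationResult",
    "DivergenceError",
    "generate_sinusoid_inputs",
    "integrate",
    "integrate_ode",
    "run_trial_pair",
    "run_figure_conditions",
    "TrialPairSummary",
]


class DivergenceError(RuntimeError):
    """Raised when a trajectory leaves the finite range; carries blow-up time."""

    def __init__(self, t: float):
        super().__init__(f"trajectory diverged (non-finite state) at t = {t:.6g}")
        self.t = t


@dataclass(frozen=True)
class Perturbation:
    """A constant additive pulse on the neural inputs.

    ``onset=None`` places the pulse window at the midpoint of the run,
    [t_end/2, t_end/2 + duration_steps * dt).
    """

    value: float = 10.0
    duration_steps: int = 100
    onset: Optional[float] = None


@dataclass(frozen=True)
class SimulationProtocol:
    """Everything needed to reproduce a run: grid, seed, inputs, noise."""

    t_end: float = 20.0
    dt: float = 1e-2
    seed: int = 0
    input: Optional[InputSpec] = None
    perturbation: Optional[Perturbation] = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    def times(self) -> np.ndarray:
        n_steps = int(round(self.t_end / self.dt))
        return np.arange(n_steps + 1) * self.dt

    def perturbation_window(self) -> Optional[tuple[float, float]]:
        if self.perturbation is None or self.perturbation.duration_steps == 0:
            return None
        onset = self.perturbation.onset
        if onset is None:
            onset = 0.5 * self.t_end
        return (onset, onset + self.perturbation.duration_steps * self.dt)


@dataclass
class SimulationResult:
    """Trajectory on a fixed grid plus the protocol that produced it.

    ``states`` has shape (len(times), n) for static-weight runs and
    (len(times), n + n^2) for plastic runs (layout [x; W row-major]).
    """

    times: np.ndarray
    states: np.ndarray
    n: int
    plastic: bool
    protocol: SimulationProtocol
    static_w: Optional[np.ndarray] = None
    rng_record: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        """Neural trajectory, shape (T, n)."""
        return self.states[:, : self.n]

    @property
    def w(self) -> np.ndarray:
        """Weight trajectory, shape (T, n, n); constant for static runs."""
        if not self.plastic:
            return np.broadcast_to(
                self.static_w, (len(self.times), self.n, self.n)
            )
        return self.states[:, self.n :].reshape(len(self.times), self.n, self.n)

    def state_at(self, index: int) -> NetworkState:
        return NetworkState(self.x[index], np.array(self.w[index]))

    def flat_states(self) -> np.ndarray:
        """Full flattened states (T, n + n^2), materialised for static runs too."""
        if self.plastic:
            return self.states
        wflat = np.tile(self.static_w.ravel(), (len(self.times), 1))
        return np.hstack([self.states, wflat])


def generate_sinusoid_inputs(
    n: int,
    dt: float,
    seed: int,
    freq_range: Optional[tuple[float, float]] = None,
    amp_range: tuple[float, float] = (0.0, 20.0),
) -> InputSpec:
    """Per-neuron sinusoid bank u_i(t) = a_i sin(2 pi f_i t + phi_i).

    Frequencies are drawn uniformly on (dt, 100 dt) by default — the protocol
    ties them to the integration step; pass ``freq_range`` for physical-units
    frequencies instead.  Phases ~ U(0, 2 pi), amplitudes ~ U(0, 20).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = freq_range if freq_range is not None else (dt, 100.0 * dt)
    return InputSpec.sinusoids(
        frequencies=rng.uniform(lo, hi, size=n),
        phases=rng.uniform(0.0, 2.0 * np.pi, size=n),
        amplitudes=rng.uniform(*amp_range, size=n),
    )


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------


def _rk4_step(f: Callable, t: float, z: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(t, z)
    k2 = f(t + 0.5 * dt, z + 0.5 * dt * k1)
    k3 = f(t + 0.5 * dt, z + 0.5 * dt * k2)
    k4 = f(t + dt, z + dt * k3)
    return z + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_ode(
    f: Callable[[float, np.ndarray], np.ndarray],
    z0: np.ndarray,
    t_end: float,
    dt: float,
    method: str = "rk4",
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step integration of dz/dt = f(t, z); returns (times, states).

    ``method`` is ``"rk4"`` (default) or ``"euler"``.  Raises
    :class:`DivergenceError` if the state goes non-finite.
    """
    n_steps = int(round(t_end / dt))
    z = np.array(z0, dtype=float)
    out = np.empty((n_steps + 1, z.shape[0]))
    out[0] = z
    for step in range(n_steps):
        t = step * dt
        if method == "rk4":
            z = _rk4_step(f, t, z, dt)
        elif method == "euler":
            z = z + dt * f(t, z)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not np.all(np.isfinite(z)):
            raise DivergenceError(t + dt)
        out[step + 1] = z
    return np.arange(n_steps + 1) * dt, out


def _effective_input(protocol: SimulationProtocol, n: int) -> Callable[[float], np.ndarray]:
    base = protocol.input if protocol.input is not None else InputSpec.none(n)
    window = protocol.perturbation_window()
    if window is None:
        return lambda t: base(t)
    t0, t1 = window
    pulse = protocol.perturbation.value * np.ones(n)

    def u(t: float) -> np.ndarray:
        val = base(t)
        if t0 <= t < t1:
            return val + pulse
        return val

    return u


def integrate(
    model: NeuralModelSpec,
    plasticity: Optional[PlasticitySpec],
    protocol: SimulationProtocol,
    initial: NetworkState,
) -> SimulationResult:
    """Integrate the combined (or static-weight) system under a protocol.

    With ``noise_sigma == 0`` this is deterministic RK4; with noise it is
    Euler–Maruyama, with sigma * dB added to the neural coordinates only.
    ``plasticity=None`` freezes W = initial.w and integrates x alone.
    """
    n = initial.n
    if model.n != n:
        raise ValueError("model size does not match initial state")
    u = _effective_input(protocol, n)
    plastic = plasticity is not None

    if plastic:
        def f(t: float, z: np.ndarray) -> np.ndarray:
            state = NetworkState.unflatten(z, n)
            return combined_rhs(state, model, plasticity, u(t), t)

        z0 = initial.flatten()
    else:
        w_static = np.array(initial.w)

        def f(t: float, z: np.ndarray) -> np.ndarray:
            return model.h(z) + w_static @ model.r(z) + u(t)

        z0 = np.array(initial.x)

    rng_record = {"seed": protocol.seed, "generator": "numpy.default_rng(PCG64)"}

    if protocol.noise_sigma == 0.0:
        times, states = integrate_ode(f, z0, protocol.t_end, protocol.dt)
    else:
        # Euler–Maruyama; independent Wiener increments per neural unit.
        rng = np.random.default_rng(protocol.seed)
        n_steps = int(round(protocol.t_end / protocol.dt))
        dt = protocol.dt
        sqrt_dt = np.sqrt(dt)
        z = np.array(z0)
        states = np.empty((n_steps + 1, z.shape[0]))
        states[0] = z
        for step in range(n_steps):
            t = step * dt
            z = z + dt * f(t, z)
            dW = rng.standard_normal(n) * sqrt_dt
            z[:n] = z[:n] + protocol.noise_sigma * dW
            if not np.all(np.isfinite(z)):
                raise DivergenceError(t + dt)
            states[step + 1] = z
        times = np.arange(n_steps + 1) * dt

    return SimulationResult(
        times=times,
        states=states,
        n=n,
        plastic=plastic,
        protocol=protocol,
        static_w=None if plastic else np.array(initial.w),
        rng_record=rng_record,
    )


# ---------------------------------------------------------------------------
# paired trials
# ---------------------------------------------------------------------------


@dataclass
class TrialPairSummary:
    """Paired trajectories with identical inputs and their distance series."""

    times: np.ndarray
    mean_distance: np.ndarray
    pair_distances: list
    results: list


def draw_initial_state(
    n: int, rng: np.random.Generator, plastic: bool, zero_diag: bool = True,
    w_static: Optional[np.ndarray] = None,
) -> NetworkState:
    """Initial conditions uniform on [-1, 1] per coordinate."""
    x0 = rng.uniform(-1.0, 1.0, size=n)
    if plastic:
        w0 = rng.uniform(-1.0, 1.0, size=(n, n))
        if zero_diag:
            np.fill_diagonal(w0, 0.0)
    else:
        w0 = np.array(w_static)
    return NetworkState(x0, w0)


def run_trial_pair(
    model: NeuralModelSpec,
    plasticity: Optional[PlasticitySpec],
    protocol: SimulationProtocol,
    n_pairs: int = 1,
    perturb_one: bool = False,
    w_static: Optional[np.ndarray] = None,
    shared_w0: Optional[np.ndarray] = None,
) -> TrialPairSummary:
    """Simulate pairs of trials with identical inputs, distinct initial states.

    Each pair shares the input bank; initial conditions are drawn
    independently.  ``perturb_one`` applies the protocol's pulse to exactly
    one member; noise (if any) is independent per member.  Returns the full
    trajectories and the flattened-state Euclidean distance series averaged
    over pairs.

    ``shared_w0`` pins W(0) to a common matrix across all trials (only the
    neural initial conditions differ), matching runs that reuse one weight
    matrix across conditions.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    n = model.n
    plastic = plasticity is not None
    rng = np.random.default_rng(protocol.seed)
    base_proto = replace(protocol, perturbation=None)

    distances = []
    results = []
    times = None
    for pair in range(n_pairs):
        members = []
        for member in range(2):
            if shared_w0 is not None:
                init = draw_initial_state(n, rng, plastic=False, w_static=shared_w0)
            else:
                init = draw_initial_state(n, rng, plastic=plastic, w_static=w_static)
            proto = protocol if (perturb_one and member == 0) else base_proto
            # independent noise per member: distinct derived seeds
            proto = replace(proto, seed=int(protocol.seed + 1000 * pair + member + 1))
            try:
                members.append(integrate(model, plasticity, proto, init))
            except DivergenceError as err:
                raise DivergenceError(err.t) from err
        a, b = members
        dist = np.linalg.norm(a.flat_states() - b.flat_states(), axis=1)
        distances.append(dist)
        results.append((a, b))
        times = a.times
    mean_distance = np.mean(np.stack(distances), axis=0)
    return TrialPairSummary(
        times=times,
        mean_distance=mean_distance,
        pair_distances=distances,
        results=results,
    )


def run_figure_conditions(
    n: int = 100,
    t_end: float = 20.0,
    dt: float = 1e-2,
    seed: int = 0,
    n_pairs: int = 1,
) -> dict:
    """The three distance-convergence conditions on one plastic fixture.

    All conditions share the same weight matrix W(0) and the same sinusoid
    input bank; only the neural initial conditions differ between trial pairs.
    Conditions: ``baseline`` (inputs only), ``pulse`` (a +10 vector on the
    neural inputs of one trial for 100 steps mid-run), ``pulse_noise``
    (the pulse plus independent sigma = 0.2 noise on each trial).
    Returns condition name -> :class:`TrialPairSummary`.
    """
    from .fixtures import random_plastic_network

    model, plasticity, state = random_plastic_network(n=n, seed=seed)
    inputs = generate_sinusoid_inputs(n, dt, seed)
    conditions = {
        "baseline": (
            SimulationProtocol(t_end=t_end, dt=dt, seed=seed, input=inputs),
            False,
        ),
        "pulse": (
            SimulationProtocol(
                t_end=t_end, dt=dt, seed=seed, input=inputs,
                perturbation=Perturbation(),
            ),
            True,
        ),
        "pulse_noise": (
            SimulationProtocol(
                t_end=t_end, dt=dt, seed=seed, input=inputs,
                perturbation=Perturbation(), noise_sigma=0.2,
            ),
            True,
        ),
    }
    return {
        name: run_trial_pair(
            model, plasticity, proto, n_pairs=n_pairs,
            perturb_one=perturb_one, shared_w0=state.w,
        )
        for name, (proto, perturb_one) in conditions.items()
    }
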