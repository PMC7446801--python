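"""Trajectory-distance analysis and weight-matrix spectral time series.

Contraction shows up empirically as an exponentially shrinking distance
between trajectories started from distinct initial conditions.  This module
measures that distance (optionally in a non-identity metric), fits the
contraction rate from the log-distance slope, and tracks the spectral
quantities of the evolving weight matrix: its spectral norm, the spectral
norm of its antisymmetric part (which the correlational rule drives to zero,
symmetrising W), and lambda_max of its symmetric part, whose staying below
the neuronal leak rate is a prerequisite for network contraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.linalg

from .dynamics import NeuralModelSpec, PlasticitySpec
from .lognorm import Metric, antisym_part, sym_part
from .simulate import SimulationResult

__all__ = [
    "DistanceSeries",
    "SpectralTrace",
    "trajectory_distance",
    "distance_series",
    "estimate_contraction_rate",
    "weight_spectral_trace",
    "bound_check",
]


@dataclass
class DistanceSeries:
    """Full-state distance between two trajectories over a shared grid."""

    times: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(self.distances < -0.0):
            raise ValueError("distances must be nonnegative")


@dataclass
class SpectralTrace:
    """Spectral summaries of W(t) along a simulated trajectory.

    bound — a theoretical envelope for lambda_max(sym(W(t))); the default is
    the forgetting-driven decay of the initial value (see
    :func:`weight_spectral_trace`), labelled implementation-derived.
    """

    times: np.ndarray
    spec_norm_w: np.ndarray
    spec_norm_antisym: np.ndarray
    lambda_max_sym: np.ndarray
    bound: np.ndarray


def trajectory_distance(
    a: SimulationResult,
    b: SimulationResult,
    metric: Optional[Metric] = None,
) -> DistanceSeries:
    """Pointwise Euclidean (or metric) distance between two trajectories.

    With a metric, distances are ||theta (z_a - z_b)||_2 on the flattened
    states; the identity metric reproduces the plain Euclidean series.
    """
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("trajectories must share the same time grid")
    za, zb = a.flat_states(), b.flat_states()
    if za.shape != zb.shape:
        raise ValueError("trajectories must have matching state dimensions")
    diff = za - zb
    if metric is not None:
        if metric.n != diff.shape[1]:
            raise ValueError("metric dimension does not match state dimension")
        diff = diff @ metric.theta.T
    return DistanceSeries(a.times, np.linalg.norm(diff, axis=1))


def distance_series(times, za, zb, theta: Optional[np.ndarray] = None) -> DistanceSeries:
    """Array-level variant of :func:`trajectory_distance` for raw trajectories."""
    diff = np.asarray(za, dtype=float) - np.asarray(zb, dtype=float)
    if theta is not None:
        diff = diff @ np.asarray(theta, dtype=float).T
    return DistanceSeries(np.asarray(times, dtype=float), np.linalg.norm(diff, axis=1))


def estimate_contraction_rate(
    d: DistanceSeries, fit_window: Optional[tuple[float, float]] = None
) -> dict:
    """Contraction rate from an OLS fit of log-distance against time.

    Returns ``{"rate": r, "r_squared": q}`` where ``r`` is the negated slope
    (positive for shrinking distances).  Distances must be strictly positive
    on the window; a zero distance makes the log fit degenerate.
    """
    if fit_window is None:
        fit_window = (float(d.times[0]), float(d.times[-1]))
    lo, hi = fit_window
    mask = (d.times >= lo) & (d.times <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError("fit window contains fewer than two samples")
    y = d.distances[mask]
    if np.any(y <= 0):
        raise ValueError("distances must be strictly positive on the fit window")
    t = d.times[mask]
    logy = np.log(y)
    slope, intercept = np.polyfit(t, logy, 1)
    resid = logy - (slope * t + intercept)
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"rate": float(-slope), "r_squared": r_squared}


def _default_bound(
    result: SimulationResult, plasticity: PlasticitySpec
) -> np.ndarray:
    """Forgetting-decay envelope lambda_max(sym W(0)) * exp(-int_0^t gamma).

    When K is PSD with positive entries the Hebbian drive -K o (x x^T) is
    negative semidefinite (Schur product of PSD matrices), so it can only
    push lambda_max(sym W) down; what remains is the forgetting decay of the
    initial value.  Implementation-derived envelope, pluggable via the
    ``bound`` argument of :func:`weight_spectral_trace`.
    """
    lam0 = float(scipy.linalg.eigvalsh(sym_part(result.w[0]))[-1])
    gammas = np.array([plasticity.gamma_at(t) for t in result.times])
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (gammas[1:] + gammas[:-1]) * np.diff(result.times))]
    )
    return lam0 * np.exp(-integral)


def weight_spectral_trace(
    result: SimulationResult,
    model: NeuralModelSpec,
    plasticity: PlasticitySpec,
    bound: Optional[Callable[[SimulationResult, PlasticitySpec], np.ndarray]] = None,
    stride: int = 1,
) -> SpectralTrace:
    """Per-time-point ||W||_2, ||antisym(W)||_2, lambda_max(sym(W)) and bound.

    ``stride`` subsamples the grid for long runs.  The antisymmetric norm
    decaying to zero means the weight matrix becomes symmetric; the overall
    spectral norm staying away from zero shows the weights have not simply
    decayed away.
    """
    if not result.plastic:
        raise ValueError("spectral trace requires a plastic (weight-carrying) run")
    idx = np.arange(0, len(result.times), max(stride, 1))
    w_traj = result.w[idx]
    spec_w = np.array([np.linalg.norm(w, 2) for w in w_traj])
    spec_anti = np.array([np.linalg.norm(antisym_part(w), 2) for w in w_traj])
    lam_sym = np.array(
        [float(scipy.linalg.eigvalsh(sym_part(w))[-1]) for w in w_traj]
    )
    bound_fn = bound if bound is not None else _default_bound
    bound_full = np.asarray(bound_fn(result, plasticity), dtype=float)
    return SpectralTrace(
        times=result.times[idx],
        spec_norm_w=spec_w,
        spec_norm_antisym=spec_anti,
        lambda_max_sym=lam_sym,
        bound=bound_full[idx] if bound_full.shape == result.times.shape else bound_full,
    )


def bound_check(
    trace: SpectralTrace,
    model: NeuralModelSpec,
    burn_in_fraction: float = 0.1,
) -> tuple[bool, np.ndarray]:
    """Is lambda_max(sym(W(t))) <= min_i beta_i after burn-in?

    This is the prerequisite for overall network contraction: the recurrent
    drive must not exceed the leak rate of the individual neurons.  Returns
    (ok, margin series beta_min - lambda_max_sym over the post-burn-in grid).
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    beta_min = float(np.min(model.beta_per_neuron))
    t_burn = trace.times[0] + burn_in_fraction * (trace.times[-1] - trace.times[0])
    mask = trace.times >= t_burn
    margins = beta_min - trace.lambda_max_sym[mask]
    return bool(np.all(margins >= 0)), margins
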