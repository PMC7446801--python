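"""Logarithmic norms (matrix measures) and contraction metrics.

The logarithmic norm mu(A) = lim_{eps->0+} (||I + eps*A|| - 1)/eps bounds the
growth rate of trajectory separation for dx/dt = A(t) x: if mu(J) <= -c < 0
along a trajectory, nearby trajectories converge at rate c.  Two induced norms
are supported:

* ``mu1`` (induced 1-norm): max over columns j of a_jj + sum_{i!=j} |a_ij|.
* ``mu2`` (induced 2-norm): largest eigenvalue of the symmetric part
  (A + A^T)/2.

A contraction *metric* M = theta^T theta generalises the Euclidean norm; a
system contracting in any metric converges in every coordinate system,
possibly after transient divergence in the identity metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "Metric",
    "mu1",
    "mu2",
    "mu2_in_metric",
    "mu_limit_oracle",
    "sym_part",
    "antisym_part",
]

#: relative tolerance for "is symmetric" checks
SYMMETRY_RTOL = 1e-10
#: smallest eigenvalue above which a matrix counts as positive definite
PD_EIG_FLOOR = 1e-12


def _as_square(a) -> np.ndarray:
    """Validate and return ``a`` as a finite square 2-d float array."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix contains non-finite entries")
    return a


@dataclass(frozen=True)
class Metric:
    """A contraction metric M = theta^T theta defined by an invertible theta.

    Parameters
    ----------
    theta:
        Invertible n x n coordinate transformation; distances are measured as
        ``||theta (za - zb)||_2``.
    """

    theta: np.ndarray = field()

    def __post_init__(self):
        theta = _as_square(self.theta)
        object.__setattr__(self, "theta", theta)
        m = theta.T @ theta
        scale = np.linalg.norm(m)
        if not np.allclose(m, m.T, rtol=0, atol=SYMMETRY_RTOL * max(scale, 1.0)):
            raise ValueError("theta^T theta is not symmetric")  # pragma: no cover
        evals = scipy.linalg.eigvalsh(m)
        if evals[0] <= PD_EIG_FLOOR * max(scale, 1.0):
            raise ValueError("metric is not positive definite: theta is singular")

    @property
    def m(self) -> np.ndarray:
        """The symmetric positive-definite metric matrix theta^T theta."""
        return self.theta.T @ self.theta

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def identity(cls, n: int) -> "Metric":
        return cls(np.eye(n))

    @classmethod
    def diagonal(cls, scales) -> "Metric":
        """Metric from per-coordinate scale factors (theta = diag(scales))."""
        scales = np.asarray(scales, dtype=float)
        return cls(np.diag(scales))


def mu1(a) -> float:
    """Logarithmic norm induced by the vector 1-norm.

    mu1(A) = max_j [a_jj + sum_{i != j} |a_ij|]  (column-indexed).
    """
    a = _as_square(a)
    col_abs = np.abs(a).sum(axis=0) - np.abs(np.diag(a))
    return float(np.max(np.diag(a) + col_abs))


def mu2(a) -> float:
    """Logarithmic norm induced by the vector 2-norm.

    mu2(A) = lambda_max((A + A^T)/2).  Uses a symmetric eigensolver on the
    symmetric part, which is exactly symmetric by construction.
    """
    a = _as_square(a)
    return float(scipy.linalg.eigvalsh(sym_part(a))[-1])


def sym_part(a) -> np.ndarray:
    """Symmetric component 0.5 (A + A^T) of the decomposition A = S + N."""
    a = _as_square(a)
    return 0.5 * (a + a.T)


def antisym_part(a) -> np.ndarray:
    """Antisymmetric component 0.5 (A - A^T); zero diagonal, N_ij = -N_ji."""
    a = _as_square(a)
    return 0.5 * (a - a.T)


def mu_limit_oracle(a, which_norm: int, epsilon: float = 1e-7) -> float:
    """Finite-difference evaluation of the limit definition of mu.

    Returns ``(||I + eps*A||_i - 1)/eps`` with the induced 1-norm (max
    absolute column sum) or induced 2-norm (largest singular value).  This is
    a one-sided forward difference at fixed ``epsilon``, intended as an
    independent oracle for :func:`mu1` / :func:`mu2`, not a production path.
    """
    a = _as_square(a)
    if not 0.0 < epsilon <= 1e-3:
        raise ValueError(f"epsilon must be in (0, 1e-3], got {epsilon}")
    m = np.eye(a.shape[0]) + epsilon * a
    if which_norm == 1:
        norm = np.max(np.abs(m).sum(axis=0))
    elif which_norm == 2:
        norm = np.linalg.norm(m, ord=2)
    else:
        raise ValueError(f"which_norm must be 1 or 2, got {which_norm!r}")
    return float((norm - 1.0) / epsilon)


def mu2_in_metric(a, metric: Metric) -> float:
    """mu2 of the Jacobian expressed in the coordinates y = theta x.

    Computes mu2(theta A theta^{-1}); with the identity metric this reduces
    exactly to ``mu2(a)``.  A system with mu2_in_metric < 0 contracts in the
    metric even if it transiently diverges in the identity metric.
    """
    a = _as_square(a)
    if metric.n != a.shape[0]:
        raise ValueError(
            f"metric dimension {metric.n} does not match matrix size {a.shape[0]}"
        )
    # theta A theta^{-1} via a linear solve on the right factor
    transformed = np.linalg.solve(metric.theta.T, (metric.theta @ a).T).T
    return mu2(transformed)
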