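"""Logarithmic norms and contraction metrics on small matrices.

A matrix measure mu(A) < 0 certifies that trajectories of dx/dt = A x (and,
applied to Jacobians, of nonlinear systems) converge toward each other.  This
example evaluates the two workhorse measures and shows how a change of metric
can reveal contraction hidden by transient divergence.
"""

import numpy as np

from contractrnn import Metric, mu1, mu2, mu2_in_metric, mu_limit_oracle

a = np.array([[-2.0, 1.0], [1.0, -2.0]])
print("A =", a.tolist())
print("mu1(A) =", mu1(a), " (column-sum measure)")
print("mu2(A) =", mu2(a), " (largest eigenvalue of the symmetric part)")
print("limit-definition oracle, 2-norm:", mu_limit_oracle(a, 2, 1e-7))
# Both are -1: every pair of trajectories of dx/dt = A x approaches at rate 1.

b = np.array([[-1.0, 10.0], [0.0, -1.0]])
print("\nB =", b.tolist())
print("mu2(B) =", mu2(b), " -> positive: distances can transiently grow")
metric = Metric.diagonal([1.0, 10.0])
print("mu2 of B in the diag(1, 10) metric =", mu2_in_metric(b, metric))
# Negative in the rescaled metric: B is contracting after all, with transient
# divergence only in the original coordinates.
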