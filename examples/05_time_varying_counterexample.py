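"""Why eigenvalues cannot certify stability of time-varying systems.

The system dx/dt = -x + e^{2t} y, dy/dt = -y has A(t) with eigenvalues
(-1, -1) frozen at every instant — yet x(t) = sinh(t) grows without bound.
mu2(A(t)), the largest eigenvalue of the symmetric part, correctly turns
positive at t = ln(2)/2 and flags the instability.
"""

import numpy as np

from contractrnn import eigenvalue_test_insufficiency_demo

demo = eigenvalue_test_insufficiency_demo(t_end=2.0, dt=1e-4)

print("eigenvalues of A(t) at all sampled times:",
      np.unique(np.round(demo["eigenvalues"], 12)).tolist())
print("x(2) integrated:", demo["trajectory"][-1, 0],
      "  sinh(2) =", np.sinh(2.0))
print("max |integrated - closed form|:", demo["max_abs_error"])
print("mu2 crosses zero at t =", demo["mu2_zero_crossing"],
      "  (ln 2 / 2 =", np.log(2) / 2, ")")
# Eigenvalues say "stable"; the trajectory and the log-norm say otherwise.
# For time-varying (and nonlinear) networks, use the symmetric part, not the
# spectrum.
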