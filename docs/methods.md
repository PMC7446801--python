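# Methods

## Model

The package studies rate networks whose joint state is the pair (x, W): the
vector of neural activations and the full synaptic weight matrix, flattened
to a single (n + n²)-dimensional state laid out as [x; rows of W].  The
neural subsystem is

    dx_i/dt = h(x_i) + Σ_j W_ij r(x_j) + u_i(t),

where x_i is interpreted as deviation from a (positive, large-enough)
baseline firing rate, so negative values are meaningful and no rectification
is applied.  The leak h must satisfy h' < 0; the implementation ships
h(x) = −βx with per-neuron leak rate β_i > 0 (default 1), and β_i doubles as
the isolated neuron's contraction rate.  Activations r are identity (gain
g_max = 1, |r| unbounded) or tanh (g_max = 1, r_max = 1); the identity case
recovers the linear-rate model as an exact special case.  Self-feedback is
folded into h; fixtures therefore zero the diagonal of W.

The synaptic subsystem is the correlational rule

    dW_ij/dt = −k_ij x_i x_j − γ(t) W_ij,

Hebbian for inhibitory synapses and anti-Hebbian for excitatory ones.  Its
two structural consequences drive everything else:

1. With symmetric K, the antisymmetric part of W obeys
   d/dt antisym(W) = −γ antisym(W), so ‖antisym W(t)‖ =
   ‖antisym W(0)‖ exp(−∫₀ᵗ γ): plasticity symmetrises the weight matrix at
   exactly the forgetting rate.  This closed form is a hard oracle for the
   integrator (tests require 1% agreement at dt = 1e−3).
2. With K positive semi-definite and entrywise positive, the Hebbian drive
   −K ∘ (x xᵀ) is negative semidefinite (Schur product of PSD matrices), so
   λ_max(sym W) can only be pushed *down* by plasticity; what remains is the
   forgetting decay of its initial value.  That is the default "bound" curve
   in the spectral trace — an implementation-derived envelope, pluggable by
   the caller.

## Stability analysis

Contraction is certified through logarithmic norms of Jacobians: μ₁ (column
version: max_j [a_jj + Σ_{i≠j} |a_ij|]) and μ₂ (λ_max of the symmetric
part, computed with a symmetric eigensolver since the symmetric part is
exactly symmetric by construction).  A brute-force oracle evaluates the
limit definition (‖I + εA‖ − 1)/ε as a one-sided forward difference at
fixed ε (default 1e−7) — deliberately naive, it exists to cross-check the
closed forms, not to be fast.  Induced norms are stated explicitly because
row/column conventions differ across texts: induced 1-norm = max absolute
column sum, induced 2-norm = largest singular value.

Metrics M = θᵀθ enter as mu2_in_metric(A) = μ₂(θAθ⁻¹).  Symmetry checks use
relative tolerance 1e−10 and positive-definiteness requires the smallest
eigenvalue of M to exceed 1e−12 (machine-precision slack on doubles).

The combined Jacobian has blocks ∂ẋ/∂x = diag(h') + W diag(r'),
∂ẋ_i/∂W_il = r(x_l), ∂Ẇ_ij/∂x_m = −k_ij(δ_im x_j + δ_jm x_i), and
∂Ẇ/∂W = −γI; it is validated against central finite differences (step 1e−6,
tolerance 1e−5) in the tests.

### Plasticity certificate and its metric

The appendix-level derivation of the contraction metric "from K" is not
reproduced here; instead the certificate uses a concrete, checkable choice:
a diagonal θ that is identity on the neural block and rescales each synaptic
coordinate W_ij by 1/√k_ij.  This is the scaling under which the
neural→synaptic and synaptic→neural cross-blocks of the transformed Jacobian
form (nearly) equal-and-opposite pairs — the negative-feedback structure
that makes combinations of contracting subsystems contracting.  The
certificate does not *assume* the metric works: it integrates an input-free
test trajectory (10 time units, dt = 1e−2, U(−1,1) initial conditions,
50 μ₂ samples) and requires μ₂ of the transformed Jacobian to be negative at
every sampled time on the trajectory tail (last half of the horizon).

The tail window is principled, not cosmetic: θ is state-independent, and for
generic U(−1,1) initial weights λ_max(sym W(0)) exceeds the unit leak rate,
so μ₂ is provably positive during the initial transient in *this* metric.
The forgetting term shrinks sym(W) below β within a couple of time units,
after which μ₂ settles near −min(β, γ).  The report carries the full μ₂
series so callers can inspect the transient.  The certificate's hypotheses —
K symmetric (rtol 1e−10), entrywise positive (strict), PSD (min eigenvalue
≥ −1e−10‖K‖), γ > 0, identity activation — are reported individually;
failures are named, never raised.

For large networks, μ₂ of the (n+n²)-dimensional transformed Jacobian is
computed matrix-free: the symmetric part has the closed-form action

    S(u, V) = ( sym(A)u − ½(√K ∘ V)ᵀx ,  −γV − ½ √K ∘ (x uᵀ) ),

evaluated through a `LinearOperator` + Lanczos (`eigsh`, largest algebraic).
Below combined dimension 900 a dense eigensolve is used; the two routes are
cross-checked against each other in the tests.

### Static-weight certificates

For frozen weights the symmetric-part test passes iff
g_max λ_max(sym W) < min β_i.  The E-I balance certificate checks Dale signs
(E→I block nonnegative, I→E nonpositive) and the relative cross-block
residual ‖W_EI + W_IEᵀ‖ ≤ tol (‖W_EI‖ + ‖W_IE‖), default tol = 0.05 for
"statistical" balance (no canonical value exists; 5% is the package's
choice), then applies the symmetric-part test to the full matrix so any
residual is automatically folded in.  Under exact balance the cross blocks
cancel identically in sym(W), making the margin invariant to cross-block
amplitude — the property the acceptance checks exercise at scales 1, 10
and 100.  All certificate inequalities are strict with zero slack; margins
are reported so callers can apply their own.

The sparsity certificate evaluates margins β_i − p_i(g_max w_max +
α_i r_max) exactly; plastic synapses (α_i > 0) require finite r_max since
the derivation assumes bounded activations — violating this raises a
precondition error rather than silently passing.

## Simulation protocols

Deterministic integration is fixed-step classical RK4; stochastic runs use
Euler–Maruyama with independent Wiener increments added to neural
coordinates only (noise perturbs firing rates, not weights).  Defaults
follow the figure-reproduction protocol: dt = 1e−2, initial conditions
uniform on [−1, 1], sinusoid input banks u_i = a_i sin(2π f_i t + φ_i) with
f_i ~ U(dt, 100 dt), φ_i ~ U(0, 2π), a_i ~ U(0, 20), a pulse of +10 on every
neural input for 100 steps starting at the midpoint, and noise σ = 0.2.
Closed-form-gated tests use dt = 1e−3.  The frequency range tied to dt is
kept verbatim for protocol fidelity (dimensionally odd as it is); a
physical-units `freq_range` override is provided.  Trial pairs share the
input bank and (optionally) W(0) while drawing independent initial
conditions; distances are full-state Euclidean norms, optionally in a
supplied metric.  Any non-finite state aborts with the blow-up time.
Horizon default is 20 time units, long enough for unit-rate fixtures to
reach terminal/initial distance ratios below 1e−3.

Problem sizes used by the acceptance script: 100 random 5×5 matrices for the
oracle; n = 20 (dt = 1e−3, t ≤ 5) for the antisymmetric-decay closed form;
n = 100 (dt = 1e−2, t ≤ 20) for the three distance-convergence conditions;
20 sparse networks (n = 30, p = 3, w_max = 0.1) × 10 trial pairs; 10+10 E-I
populations.  These sizes exhibit the asymptotic behaviour while keeping
each pipeline in the seconds-to-a-minute range.

## Contraction-rate estimation

Rates are the negated OLS slope of log-distance against time (no robust
regression).  Fits exclude the first 10% of the run by default — the
transient during which λ_max(sym W) may still exceed β.  The rate is only
meaningful when distances are strictly positive on the window; zero
distances raise a degenerate-fit error.  A bound −c from the log-norm series
is exposed only when μ ≤ −c < 0 holds over the sampled trajectory;
otherwise the result is "no certificate", since a supremum of |μ| is a rate
only for uniformly negative μ.

## Synthetic fixtures: what they do and do not emulate

Fixtures are seeded and bit-reproducible.  They emulate the study
conditions — uniform weights and activations on [−1, 1], equal learning
rates, exact or mean-matched E-I balance, exact per-neuron afferent counts —
not biological realism: there are no empirically calibrated connectomes, no
distance-dependent topology, no synaptic delays, no spiking.  Passing tests
therefore demonstrate the *mechanisms* (plasticity-induced symmetrisation,
sparsity margins, balance cancellation) on idealised networks, not that any
particular biological circuit is contracting.  Within-population E-I weights
respect Dale's principle by column sign, which the general theory does not
require but the two-population analysis presumes.

## Known limitations and deliberate discrepancies

- The time-varying counterexample is implemented against the printed matrix
  [[−1, e^{2t}], [0, −1]], whose eigenvalues are (−1, −1) (triangular) and
  whose solution y = y(0)e^{−t} the integrator reproduces to 1e−13.  A
  published statement of its eigenvalues as "(−1, 1)" is inconsistent with
  that matrix and is not adopted.
- The plasticity certificate's metric is an implementation choice verified
  numerically per network, not a general proof; its verification trajectory
  is input-free.  Input-driven contraction is assessed empirically through
  the trial-pair distance diagnostics (and holds in all shipped
  configurations).
- The rule's drive term has no weight dependence, so no a-priori bound on
  |W| is asserted; runs report the empirical weight norms instead.
- Only induced 1- and 2-norm logarithmic norms are provided, for real
  matrices; no adaptive or stiff solvers, no delay equations, no
  region-of-contraction estimation for trained RNNs.
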