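"""Sparse connectivity as a stability mechanism.

If every neuron receives at most p afferent synapses of amplitude at most
w_max (fraction alpha of them plastic), then p (g_max w_max + alpha r_max) <
beta guarantees contraction.  The margin shrinks linearly as connectivity
densifies — sparsity buys stability.
"""

from contractrnn import NeuralModelSpec, SparsityProfile, sparsity_certificate
from contractrnn.fixtures import sparse_static_network

model = NeuralModelSpec(n=1, activation="tanh", beta=1.0)
for p in (0, 1, 2):
    report = sparsity_certificate(model, SparsityProfile([p], [0.5], w_max=0.1))
    print(f"p={p}: margin {report.margins[0]:+.2f}  passed={report.passed}")
# p=1 leaves margin 0.40; p=2 overloads the unit leak budget (margin -0.20).

print("\nmargin vs afferent count for a 30-neuron static network:")
for p in (0, 3, 6, 9):
    model, profile, _ = sparse_static_network(30, p, w_max=0.1, seed=0)
    report = sparsity_certificate(model, profile)
    print(f"  p={p}: margin {report.margin:+.2f}")
# Affine decrease with slope -g_max * w_max = -0.1 per extra synapse.
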