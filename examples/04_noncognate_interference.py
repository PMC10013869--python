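"""Noncognate competition: cognate fractions, the sharpness envelope, and
the value of proofreading.

Noncognate activators unbind only ~100x faster than cognate ones (the
affinity factor alpha), so at high noncognate-to-cognate concentration
ratios w/c most binding events are "wrong".  Equilibrium circuits are
pinned to specificity f = alpha; energy dissipation can proofread up to
f = alpha^(N_A + 1).
"""

from burstinfo import (
    CircuitSpec,
    Concentrations,
    SweepConfig,
    cognate_fraction,
    decision_time,
    maximize_metric,
    sharpness_envelope,
)

ALPHA = 100.0
print("cognate share of binding events, p_c = alpha/(alpha + w/c):")
for organism, wc in [("fly embryo", 47.0), ("worm", 698.0), ("mouse", 1426.0)]:
    print(f"  {organism:<11} w/c = {wc:6.0f}:  p_c = {cognate_fraction(ALPHA, wc):.3f}")

print()
print("observed-sharpness ceilings at w/c = 1000 (envelope S <= f/(w/c+f) S0):")
print(f"  equilibrium  (f = alpha,   S0 = 1): {sharpness_envelope(1.0, ALPHA, 1e3):.2f}")
print(f"  proofreading (f = alpha^2, S0 = 1): {sharpness_envelope(1.0, ALPHA**2, 1e3):.2f}")

print()
print("minimum decision time at w/c = 1400 (mouse-like interference):")
cfg = dict(n_init=3000, n_generations=150, n_elite=20)
conc = Concentrations(c=1.0, w=1400.0)
for na in (1, 2):
    spec = CircuitSpec(n_activation_steps=na, include_noncognate=True)
    r = maximize_metric(spec, "IR", SweepConfig(seed=2, **cfg), conc)
    t = decision_time(r.summary["IR_nats"])
    print(f"  N_A = {na}: {t:7.0f} burst cycles  (specificity f = {r.summary['f']:.0f})")
print()
print("A second activation step buys a proofreading cycle: specificity rises")
print("far above alpha and the decision time collapses by an order of magnitude.")
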