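"""Trace the energy-information boundary by parameter sweep.

How fast can the four-state circuit transmit information at a given energy
budget?  An equilibrium-constrained sweep (detailed balance built in) finds
the zero-dissipation plateau; an unconstrained sweep shows how dissipation
lifts it, with the optimum reached near ~20 kT per burst cycle.
"""

from burstinfo import CircuitSpec, SweepConfig, decision_time, maximize_metric

spec = CircuitSpec()
budget = dict(n_init=3000, n_generations=150, n_elite=20)

eq = maximize_metric(spec, "IR", SweepConfig(seed=11, equilibrium_only=True, **budget))
neq = maximize_metric(spec, "IR", SweepConfig(seed=11, **budget))

print("four-state information-rate limits (delta_c/c* = 0.1):")
print(f"  equilibrium:    {eq.value:.5f} bits/burst  "
      f"(S={eq.summary['S']:.2f}, P={eq.summary['P']:.2f}, "
      f"Phi={eq.summary['phi_per_burst']:.1e} kT/burst)")
print(f"  nonequilibrium: {neq.value:.5f} bits/burst  "
      f"(S={neq.summary['S']:.2f}, P={neq.summary['P']:.2f}, "
      f"Phi={neq.summary['phi_per_burst']:.1f} kT/burst)")
print(f"  decision times: {decision_time(eq.summary['IR_nats']):.0f} vs "
      f"{decision_time(neq.summary['IR_nats']):.0f} burst cycles")
print()
print("Dissipating roughly one-to-two ATPs' worth of free energy per burst")
print("doubles the achievable sharpness (S: 1 -> 2) while keeping the")
print("equilibrium precision (P = 1/2), a ~4x faster decision.")
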