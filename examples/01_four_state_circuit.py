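"""Build the minimal bursty gene-circuit model and inspect its thermodynamics.

One activator binding site, one activation step: four states arranged in a
cycle.  With all interaction factors eta = 1 the cycle obeys detailed
balance; making the bound activator speed up activation (eta_ab > 1)
without the compensating factors breaks it, driving a net cycle flux that
dissipates free energy.
"""

from burstinfo import (
    CircuitSpec,
    Concentrations,
    RateParameters,
    build_rate_matrix,
    detailed_balance_residual,
    solve_circuit,
)

spec = CircuitSpec()  # N_B = 1 binding site, N_A = 1 activation step
conc = Concentrations()  # cognate activator at the midpoint concentration c*

for label, params in [
    ("equilibrium (all eta = 1)", RateParameters()),
    ("driven (eta_ab = 10)", RateParameters(eta_ab=10.0)),
]:
    m = build_rate_matrix(spec, params, conc)
    sol = solve_circuit(m)
    print(f"{label}:")
    print(f"  states (n_c, n_w, m): {m.states}")
    print(f"  stationary occupancies: {[round(float(x), 4) for x in sol.pi]}")
    print(f"  cycle affinity (kT): {detailed_balance_residual(m):.4f}")
    print(f"  net cycle flux J: {sol.J:.4f} per unit time")
    print(f"  burst cycle time tau_b: {sol.tau_b:.4f} time units")
    print(f"  dissipation: {sol.phi_per_burst:.4f} kT per burst cycle")
    print()

print("The affinity ln(eta_ab eta_ua / (eta_ib eta_ba)) is the free energy")
print("spent per completed cycle; dissipation = flux x affinity, and it")
print("vanishes exactly when the cycle satisfies detailed balance.")
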