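"""Score a circuit's input-output function: sharpness, precision, information.

The normalized sharpness S is the Hill coefficient of an equivalently sharp
input-output curve; the normalized precision P summarizes how quiet the
burst noise is at the working occupancy.  Together they set the rate at
which the gene transmits information about a 10% concentration difference,
and hence the minimum number of burst cycles a downstream decision needs.
"""

from burstinfo import CircuitSpec, RateParameters, summarize

spec = CircuitSpec()
# a strongly activating but equilibrium-compatible parameter choice
params = RateParameters(k_b=2.0, k_u=2.0, k_a=0.5, k_i=1.5,
                        eta_ab=8.0, eta_ib=0.25)

rs = summarize(spec, params)
print(f"ON occupancy pi_a:            {rs.pi_a:.4f}")
print(f"mean mRNA rate r_bar:         {rs.r_bar:.4f} (units of r0)")
print(f"burst cycle time tau_b:       {rs.tau_b:.4f} time units")
print(f"dissipation per burst:        {rs.phi_per_burst:.4f} kT")
print(f"normalized sharpness S:       {rs.S:.4f}  (<= 1 at equilibrium)")
print(f"normalized precision P:       {rs.P:.4f}  (<= 1/2 at equilibrium)")
print(f"information rate:             {rs.ir_bits:.5f} bits per burst")
print(f"minimum decision time:        {rs.decision_time:.1f} burst cycles")
print()
print("The decision time is the sequential-test bound for telling a 10%")
print("concentration difference apart at a 32% error tolerance.")
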