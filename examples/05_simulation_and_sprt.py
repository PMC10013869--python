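"""Simulate burst trajectories and run sequential decision experiments.

Exact (Gillespie) simulation provides the package's synthetic data: binary
ON/OFF burst traces and accumulated-mRNA trajectories under the two
hypothesis concentrations.  A sequential probability ratio test on the
integrated output validates the analytic decision-time bound.
"""

import numpy as np

from burstinfo import (
    CircuitSpec,
    Concentrations,
    RateParameters,
    build_rate_matrix,
    decision_time,
    estimate_metrics,
    gillespie,
    sprt_decision_times,
    summarize,
)

spec = CircuitSpec()
params = RateParameters(k_b=2.0, k_u=2.0, k_a=0.5, k_i=1.5,
                        eta_ab=8.0, eta_ib=0.25)
m = build_rate_matrix(spec, params, Concentrations())

trajs = [gillespie(m, 500.0, seed=s) for s in range(10)]
est = estimate_metrics(trajs, seed=0)
rs = summarize(spec, params)
print("empirical vs analytic (10 trajectories x 500 time units):")
print(f"  ON occupancy: {est['pi_a']:.3f} +/- {est['pi_a_se']:.3f}  (analytic {rs.pi_a:.3f})")
print(f"  burst time:   {est['tau_b']:.3f} +/- {est['tau_b_se']:.3f}  (analytic {rs.tau_b:.3f})")
print(f"  variance rate:{est['v']:.4f} +/- {est['v_se']:.4f}  (analytic {rs.v:.4f})")

t, acc = trajs[0].mrna_trace(r0=1.0)
print(f"  accumulated mRNA after t={t[-1]:.0f}: {acc[-1]:.1f} "
      f"(expected ~{rs.r_bar * t[-1]:.1f})")

res = sprt_decision_times(spec, params, n_rep=200, seed=7)
pred = decision_time(rs.ir_nats, 0.32)
print()
print("sequential probability ratio test (c0 = 0.95, c1 = 1.05, eps = 0.32):")
print(f"  mean decision time: {res['mean_decision_time']:.1f} bursts "
      f"(analytic bound {pred:.1f})")
print(f"  realized error rate: {res['error_rate']:.3f} (target 0.32)")
print()
print("The empirical mean time tracks the bound because the integrated burst")
print("output is close to Gaussian at these occupancies and timescales.")
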