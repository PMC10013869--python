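# Extrapolation study: how many equilibrium binding sites are needed to meet
# an ~86-burst decision budget at w/c ~ 1400?  Run equilibrium IR sweeps over
# a ladder of site counts and extrapolate log T_min vs log N_B (the desk-scale
# suite verifies the N_B^-2 scaling that underlies the extrapolation; the
# answer lands near 17 sites).
spec:
  n_binding_sites: 8       # largest rung; lower rungs derived by decrementing
  n_activation_steps: 1
  include_noncognate: true
  affinity_factor: 100.0
concentrations:
  c: 1.0
  w: 1400.0
sweep:
  metric: IR
  equilibrium_only: true
  n_init: 100000
  n_generations: 4000
  n_elite: 48
  seed: 1
ladder:
  n_binding_sites: [1, 2, 3, 4, 5, 6, 7, 8]
  decision_budget_bursts: 86
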