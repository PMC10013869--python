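# Full-scale scan: five equilibrium binding sites under heavy noncognate
# interference (w/c ~ 1400), where the best equilibrium circuits still need
# on the order of 1,100 burst cycles to decide.
spec:
  n_binding_sites: 5
  n_activation_steps: 1
  include_noncognate: true
  affinity_factor: 100.0
concentrations:
  c: 1.0
  w: 1400.0
sweep:
  metric: IR
  equilibrium_only: true
  n_init: 200000
  n_generations: 5000
  n_elite: 64
  seed: 1
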