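# Full-scale scan of the nonequilibrium-over-equilibrium IR gain versus
# noncognate load, out to w/c = 1e5 where the gain reaches ~1000x.
spec:
  n_binding_sites: 1
  n_activation_steps: 1
  include_noncognate: true
  affinity_factor: 100.0
scan:
  w_over_c: [1.0, 10.0, 100.0, 1000.0, 10000.0, 100000.0]
sweep:
  metric: IR
  n_init: 100000
  n_generations: 4000
  n_elite: 48
  seed: 1
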