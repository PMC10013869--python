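# Full-scale sweep: one binding site, four activation steps (ten states).
# Away from equilibrium this architecture reaches decision times near
# 8 burst cycles at dissipation rates of at least ~180 k_BT per burst;
# resolving that boundary needs far longer sweeps than the test suite runs.
spec:
  n_binding_sites: 1
  n_activation_steps: 4
  include_noncognate: false
sweep:
  metric: IR
  equilibrium_only: false
  n_init: 200000
  n_generations: 5000
  n_elite: 64
  seed: 1
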