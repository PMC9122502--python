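# Self-contained demo configuration for `sdmal run-all`.
# All inputs are generated by the synthetic_data module from this seed.
seed: 11
fixtures:
  n: 9              # focal-panel haplotypes
  S: 200            # segregating sites in the focal sweep panel
  region_length: 200000
  t_sweep: 0.05     # sweep onset, units of 4*Ne generations
windows:
  width: 20000      # bp per scan window
abc:
  n_accept: 60      # accepted posterior draws (demo scale)
  reps_per_draw: 60 # coalescent replicates averaged per draw
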