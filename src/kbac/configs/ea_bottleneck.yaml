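# Literature-inspired placeholder parameters for a European-American-like
# multi-epoch bottleneck model (ancestral size, out-of-Africa bottleneck,
# re-expansion).  Values are plausible round numbers, not exact estimates.
demography:
  kind: epochs
  epochs:
    - [7778, 1]        # ancestral
    - [600, 400]       # bottleneck
    - [12500, 2000]    # recovery
    - [25000, 300]     # recent growth
selection:
  dfe_shape: 0.184
  dfe_scale: 0.234
  dominance: 0.5
  fraction_neutral: 0.0
mutation_rate: 1.8e-8
locus_length: 1500
rescale: 50
n_pools: 100
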