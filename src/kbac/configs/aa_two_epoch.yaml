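# Literature-inspired placeholder parameters for an African-American-like
# demographic and selection model (values in the spirit of published human
# NS-mutation estimates; not a claim of exact provenance).
#
# Demography: simple two-epoch model -- ancestral diploid size, then an
# instantaneous expansion `duration` generations before the present.
demography:
  kind: two_epoch
  n_ancestral: 7778
  n_current: 25636
  duration: 6809
# Gamma distribution of (positive) selection coefficients of new deleterious
# NS mutations; mean s = shape * scale ~= 0.043, additive dominance.
selection:
  dfe_shape: 0.184
  dfe_scale: 0.234
  dominance: 0.5
  fraction_neutral: 0.0
# Per-bp per-generation mutation rate and locus length (average human coding
# region ~ 1500 bp).
mutation_rate: 1.8e-8
locus_length: 1500
# Desk-scale rescaling factor: sizes and durations / c, mu and s * c.
rescale: 50
n_pools: 100
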