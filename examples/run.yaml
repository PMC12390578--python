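# Analysis run configuration: wild strains map to their susceptible reference
# colonies, formulated products to their technical-grade standards.
reference_map:
  Fogg Rd: CQ1
  Vic Fazio: KNWR
pairings:
  Deltagard: deltamethrin
  Fyfanon EW: malathion
n_boot: 1000
seed: 42
ci_method: percentile      # or bca
resample_unit: replicates  # or time_points
include_t0: true
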